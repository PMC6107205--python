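import numpy as np
import pytest

from histoscore.classifier import CallableClassifier
from histoscore.errors import DegenerateVectorError, InvalidArgumentError
from histoscore.schemes import ASHCROFT, INFLAMMATION
from histoscore.scoring import (
    ScoreMap,
    TileScore,
    is_ignored,
    read_tile_scores,
    render_score_map,
    renormalize,
    score_tile_grid,
    slide_score,
    tile_score,
    write_tile_scores,
)
from histoscore.synthetic import blue_dominant_fraction, generate_virtual_slide
from histoscore.tiling import SlideImage, slice_tiles


def brute_force_score(p, scheme):
    """Independent arithmetic oracle: plain-Python ignore rule, renormalize,
    dot product."""
    score_probs = list(p[:-1])
    if p[-1] > max(score_probs):
        return None
    total = sum(score_probs)
    return sum(w * (pi / total) for w, pi in zip(scheme.weights, score_probs))


class TestIgnoreRule:
    def test_dominant_ignore_mass_gates_the_tile(self):
        p = [0.08, 0.08, 0.08, 0.08, 0.08, 0.6]
        assert is_ignored(p, ASHCROFT)

    def test_one_hot_score_class_is_scored(self):
        assert not is_ignored([1, 0, 0, 0, 0, 0], ASHCROFT)

    def test_tie_with_score_class_resolves_to_scoring(self):
        assert not is_ignored([0.5, 0, 0, 0, 0, 0.5], ASHCROFT)
        ts = tile_score([0.5, 0, 0, 0, 0, 0.5], ASHCROFT)
        assert not ts.ignored and ts.score == pytest.approx(0.0)

    def test_wrong_length_vector_rejected(self):
        with pytest.raises(InvalidArgumentError):
            is_ignored([0.5, 0.5], ASHCROFT)


class TestRenormalize:
    def test_even_split_stays_even(self):
        p = [0, 0.5, 0.5, 0, 0, 0]
        assert renormalize(p, ASHCROFT) == pytest.approx([0, 0.5, 0.5, 0, 0])

    def test_zero_ignore_mass_is_identity(self):
        p = [0.1, 0.2, 0.3, 0.25, 0.15, 0]
        assert renormalize(p, ASHCROFT) == pytest.approx(p[:-1])

    def test_worked_arithmetic(self):
        p = [0.1, 0.2, 0.3, 0.2, 0.1, 0.1]
        expected = np.array([1, 2, 3, 2, 1]) / 9
        assert renormalize(p, ASHCROFT) == pytest.approx(expected, abs=1e-12)

    def test_renormalized_sums_to_one(self, rng):
        for _ in range(200):
            p = rng.dirichlet(np.ones(6))
            if is_ignored(p, ASHCROFT):
                continue
            assert renormalize(p, ASHCROFT).sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_score_mass_zero_is_degenerate(self):
        with pytest.raises(DegenerateVectorError):
            renormalize([0, 0, 0, 0, 0, 1.0], ASHCROFT)


class TestTileScore:
    def test_worked_example_interpolates_to_two(self):
        """A 50/50 split between classes 1 and 3 scores 0.5*1 + 0.5*3 = 2."""
        ts = tile_score([0, 0.5, 0.5, 0, 0, 0], ASHCROFT)
        assert not ts.ignored
        assert ts.score == pytest.approx(2.0, abs=1e-15)

    def test_one_hot_extremes(self):
        assert tile_score([0, 0, 0, 0, 1, 0], ASHCROFT).score == pytest.approx(7.0)
        assert tile_score([1, 0, 0, 0, 0, 0], ASHCROFT).score == pytest.approx(0.0)

    def test_mixed_vector_matches_arithmetic_oracle(self):
        p = [0.1, 0.2, 0.3, 0.2, 0.1, 0.1]
        assert tile_score(p, ASHCROFT).score == pytest.approx(28 / 9, abs=1e-12)

    def test_score_bounds_on_random_simplex(self, rng):
        for _ in range(500):
            p = rng.dirichlet(np.ones(6) * rng.uniform(0.2, 3))
            ts = tile_score(p, ASHCROFT)
            if not ts.ignored:
                assert ASHCROFT.min_weight <= ts.score <= ASHCROFT.max_weight

    def test_two_class_interpolation_is_monotone_in_lambda(self):
        """Mass split lam/(1-lam) between classes 1 and 3 moves the score
        strictly from weight 1 to weight 3."""
        lams = np.linspace(0.01, 0.99, 25)
        scores = [
            tile_score([0, 1 - lam, lam, 0, 0, 0], ASHCROFT).score for lam in lams
        ]
        assert all(1 < s < 3 for s in scores)
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_ignore_mass_invariance_identity(self, rng):
        """Adding ignore mass eps and scaling score mass by (1-eps) leaves the
        renormalized weighted sum unchanged (exact algebraic identity)."""
        weights = np.array(ASHCROFT.weights)
        for _ in range(200):
            base = rng.dirichlet(np.ones(5))
            a0 = float(weights @ base)
            for eps in (0.1, 0.5, 0.89):
                p = np.concatenate([(1 - eps) * base, [eps]])
                a_eps = float(weights @ renormalize(p, ASHCROFT))
                assert a_eps == pytest.approx(a0, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_vectors(self, rng):
        for _ in range(2000):
            p = rng.dirichlet(np.ones(6))
            ts = tile_score(p, ASHCROFT)
            expected = brute_force_score(p, ASHCROFT)
            if expected is None:
                assert ts.ignored
            else:
                assert ts.score == pytest.approx(expected, abs=1e-12)

    def test_inflammation_scheme_uses_its_own_weights(self):
        ts = tile_score([0, 0, 0.5, 0.5, 0], INFLAMMATION)
        assert ts.score == pytest.approx(2.5)


class TestSlideScore:
    def test_mean_over_scored_tiles(self):
        tiles = [TileScore(0, 0, False, 2.0), TileScore(0, 1, False, 4.0)]
        sc = slide_score(tiles)
        assert sc.mean == pytest.approx(3.0) and sc.n_scored == 2 and sc.n_ignored == 0

    def test_ignored_tiles_are_excluded(self):
        tiles = [
            TileScore(0, 0, False, 2.0),
            TileScore(0, 1, False, 4.0),
            TileScore(1, 0, True, None),
        ]
        sc = slide_score(tiles)
        assert sc.mean == pytest.approx(3.0) and sc.n_ignored == 1

    def test_all_ignored_is_an_explicit_sentinel(self):
        sc = slide_score([TileScore(0, 0, True, None)])
        assert sc.all_ignored and sc.mean is None and sc.n_ignored == 1

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            slide_score([])

    def test_tile_score_averaging_equals_probability_averaging(self, rng):
        """By linearity of the weighted sum, averaging tile scores equals
        scoring the average of the renormalized probability vectors."""
        weights = np.array(ASHCROFT.weights)
        ps = [np.concatenate([rng.dirichlet(np.ones(5)), [0.0]]) for _ in range(50)]
        mean_of_scores = np.mean([tile_score(p, ASHCROFT).score for p in ps])
        score_of_mean = weights @ np.mean([renormalize(p, ASHCROFT) for p in ps], axis=0)
        assert mean_of_scores == pytest.approx(score_of_mean, abs=1e-12)


class TestScoreMapRendering:
    PX = 96

    def _one_hot_classifier(self):
        def fn(tile):
            hot = np.zeros(6)
            hot[4 if blue_dominant_fraction(tile) > 0.3 else 0] = 1.0
            return hot

        return CallableClassifier(ASHCROFT.all_labels, fn)

    def test_checkerboard_end_to_end(self, tmp_path):
        field = [["0", "7"], ["7", "0"]]
        slide, _ = generate_virtual_slide(2, 2, field, seed=3, tile_px=self.PX)
        grid = slice_tiles(SlideImage(slide), self.PX)
        smap = score_tile_grid(self._one_hot_classifier(), grid, ASHCROFT)
        assert smap.scores == pytest.approx(np.array([[0.0, 7.0], [7.0, 0.0]]))
        out = tmp_path / "map.png"
        render_score_map(smap, out)
        assert out.stat().st_size > 0

    def test_map_grid_matches_tile_grid(self):
        field = np.full((3, 5), "0", dtype=object)
        slide, _ = generate_virtual_slide(5, 3, field, seed=1, tile_px=self.PX)
        grid = slice_tiles(SlideImage(slide), self.PX)
        smap = score_tile_grid(self._one_hot_classifier(), grid, ASHCROFT)
        assert (smap.n_rows, smap.n_cols) == (3, 5)

    def test_all_ignored_map_renders_neutral(self, tmp_path):
        smap = ScoreMap(np.full((2, 2), np.nan), ASHCROFT)
        out = tmp_path / "neutral.png"
        render_score_map(smap, out)
        assert out.exists()
        assert slide_score(smap).all_ignored

    def test_empty_map_rejected(self):
        with pytest.raises(InvalidArgumentError):
            render_score_map(ScoreMap(np.empty((0, 0)), ASHCROFT))

    def test_tile_score_csv_round_trip(self, tmp_path):
        scores = np.array([[0.5, np.nan], [3.25, 7.0]])
        smap = ScoreMap(scores, ASHCROFT)
        path = tmp_path / "scores.csv"
        write_tile_scores(smap, path)
        back = read_tile_scores(path, "ashcroft")
        assert np.isnan(back.scores[0, 1])
        assert back.scores[1, 1] == pytest.approx(7.0)
        assert back.scores[1, 0] == pytest.approx(3.25, abs=5e-4)  # 3-decimal CSV
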