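"""Ground-truth tissue generation and the disease-effect process."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stereosim.cohort import (
    DEFAULT_SIZE_DISTRIBUTION,
    CohortSpec,
    DiseaseEffect,
    LognormalMixture,
    TissueModel,
    apply_disease_effect,
    draw_true_count,
    export_tissue_csv,
    generate_tissue,
    load_tissue_csv,
)
from stereosim.errors import ConfigurationError

SINGLE = LognormalMixture((1.0,), (600.0,), (0.3,))


def small_spec(**kw):
    defaults = dict(
        genotype="wild-type", age_weeks=12, n_animals=3, mean_true_count=1000,
        between_animal_cv=0.0, size_distribution=SINGLE,
        extent=(300.0, 300.0, 120.0), seed=0,
    )
    defaults.update(kw)
    return CohortSpec(**defaults)


class TestGenerateTissue:
    def test_zero_cv_gives_exact_count(self):
        tissue = generate_tissue(small_spec(), 0)
        assert tissue.true_count == 1000

    def test_positions_and_volumes_valid(self):
        tissue = generate_tissue(small_spec(), 1)
        tissue.validate()  # inside extent, volumes positive
        assert tissue.positions.shape == (1000, 3)

    def test_deterministic_given_seed_and_index(self):
        a = generate_tissue(small_spec(), 2)
        b = generate_tissue(small_spec(), 2)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.volumes, b.volumes)

    def test_different_animals_differ(self):
        a = generate_tissue(small_spec(), 0)
        b = generate_tissue(small_spec(), 1)
        assert not np.array_equal(a.positions, b.positions)

    def test_animal_index_out_of_range(self):
        with pytest.raises(ConfigurationError):
            generate_tissue(small_spec(), 3)

    def test_count_distribution_matches_group_statistics(self, rng):
        # 200 per-animal draws against the 12-week wild-type group scale:
        # mean 993891, between-animal CV 0.116 (SD ~ 115291)
        mean, cv, n = 993891.0, 0.116, 200
        counts = np.array([draw_true_count(mean, cv, rng) for _ in range(n)])
        sem = mean * cv / np.sqrt(n)
        assert abs(counts.mean() - mean) <= 2 * sem
        assert abs(counts.std(ddof=1) / counts.mean() - cv) < 0.25 * cv


class TestMixture:
    def test_invalid_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            LognormalMixture((0.5, 0.4), (600.0, 1100.0), (0.3, 0.3))

    def test_default_mixture_spans_analysis_range(self, rng):
        v = DEFAULT_SIZE_DISTRIBUTION.sample(20000, rng)
        # bulk of the population inside the 100-1500 µm³ range
        assert np.mean((v > 100) & (v < 1500)) > 0.95
        # the 550-1050 µm³ band holds a substantial share, per the closed form
        p_band = DEFAULT_SIZE_DISTRIBUTION.band_probability(550, 1050)
        assert abs(np.mean((v >= 550) & (v < 1050)) - p_band) < 0.02

    def test_band_probability_closed_form_vs_empirical(self, rng):
        mix = LognormalMixture((0.7, 0.3), (500.0, 900.0), (0.2, 0.4))
        v = mix.sample(50000, rng)
        assert abs(np.mean((v >= 400) & (v < 800)) - mix.band_probability(400, 800)) < 0.01


class TestDiseaseEffect:
    def test_identity_effect_is_exact_identity(self, rng):
        tissue = generate_tissue(small_spec(), 0)
        out = apply_disease_effect(tissue, DiseaseEffect.identity(), rng)
        assert out.true_count == tissue.true_count
        np.testing.assert_array_equal(out.volumes, tissue.volumes)
        np.testing.assert_array_equal(out.alive, tissue.alive)

    def test_input_tissue_unmodified(self, rng):
        tissue = generate_tissue(small_spec(), 0)
        before = tissue.volumes.copy()
        apply_disease_effect(tissue, DiseaseEffect.banded(loss=0.5, atrophy=0.5), rng)
        np.testing.assert_array_equal(tissue.volumes, before)
        assert tissue.true_count == 1000

    def test_uniform_loss_matches_binomial_expectation(self):
        # 12.7% uniform removal: pooled survivors over repeats within 3σ
        loss = 0.127
        spec = small_spec(mean_true_count=20000)
        effect = DiseaseEffect.uniform(loss=loss)
        total_n, survivors = 0, 0
        for rep in range(10):
            tissue = generate_tissue(spec, 0)
            out = apply_disease_effect(tissue, effect, np.random.default_rng(rep))
            total_n += tissue.true_count
            survivors += out.true_count
        expected = (1 - loss) * total_n
        sigma = np.sqrt(total_n * loss * (1 - loss))
        assert abs(survivors - expected) <= 3 * sigma

    def test_banded_loss_confined_to_band(self, rng):
        tissue = generate_tissue(small_spec(mean_true_count=5000), 0)
        effect = DiseaseEffect.banded(loss=1.0, atrophy=1.0, band=(550.0, 1050.0))
        out = apply_disease_effect(tissue, effect, rng)
        removed = tissue.alive & ~out.alive
        assert np.all((tissue.volumes[removed] >= 550) & (tissue.volumes[removed] < 1050))
        outside = ~((tissue.volumes >= 550) & (tissue.volumes < 1050))
        assert np.all(out.alive[outside])

    @given(loss=st.floats(0.0, 1.0), seed=st.integers(0, 100))
    def test_loss_is_monotone(self, loss, seed):
        tissue = generate_tissue(small_spec(mean_true_count=500), 0)
        out = apply_disease_effect(
            tissue, DiseaseEffect.uniform(loss=loss), np.random.default_rng(seed)
        )
        assert out.true_count <= tissue.true_count

    def test_invalid_probability_rejected(self, rng):
        tissue = generate_tissue(small_spec(), 0)
        bad = DiseaseEffect(
            loss_probability=lambda v: np.full_like(v, 1.5),
            atrophy_fraction=lambda v: np.ones_like(v),
        )
        with pytest.raises(ConfigurationError):
            apply_disease_effect(tissue, bad, rng)


def test_tissue_csv_roundtrip(tmp_path):
    tissue = generate_tissue(small_spec(mean_true_count=50), 0)
    path = tmp_path / "tissue.csv"
    export_tissue_csv(tissue, "wt-00", path)
    loaded = load_tissue_csv(path, extent=tissue.extent)
    assert loaded.true_count == tissue.true_count
    np.testing.assert_allclose(loaded.positions, tissue.positions, atol=1e-3)
    np.testing.assert_allclose(loaded.volumes, tissue.volumes, atol=1e-3)
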