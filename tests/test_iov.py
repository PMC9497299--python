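"""IOV orchestration and paired statistics against hand/enumeration oracles."""

import numpy as np
import pandas as pd
import pytest

import consenseg as cs
from consenseg import (
    BinaryMask,
    ImageGrid,
    compare_modalities,
    compute_iov,
    correlate_threshold_volume,
)
from consenseg.iov import IOVStudy
from consenseg.simulate import (
    LesionPhantomSpec,
    ObserverErrorModel,
    make_phantom,
    make_study,
    simulate_observers,
)
from oracles import exact_wilcoxon_p, spearman_rho_oracle


def _records_from_pairs(values_a, values_b, metric_col="dice"):
    rows = []
    for i, (va, vb) in enumerate(zip(values_a, values_b)):
        for modality, v in (("MRI", va), ("MRI_PET", vb)):
            rows.append(
                {
                    "lesion_id": f"l{i // 3}",
                    "observer_id": f"obs{i % 3}",
                    "modality": modality,
                    metric_col: v,
                }
            )
    df = pd.DataFrame(rows)
    for col in ("dice", "hausdorff_mm", "volume_cm3"):
        if col not in df:
            df[col] = 0.5
    return df


class TestComputeIOV:
    def _unanimous_study(self):
        grid = ImageGrid((24, 24, 16), (4.0, 4.0, 5.0))
        truth = make_phantom(
            LesionPhantomSpec(
                grid=grid, lesion_center=(48.0, 48.0, 40.0), semi_axes=(20.0, 18.0, 16.0)
            )
        )[0]
        perfect = ObserverErrorModel(
            mode="iid_flip", sensitivity=(0.999999,), specificity=(0.999999,), seed=0
        )
        return {
            "lesion01": {
                m: simulate_observers(truth, perfect, 3, modality=m)
                for m in ("MRI", "MRI_PET")
            }
        }

    def test_unanimous_observers_score_perfectly(self):
        records = compute_iov(self._unanimous_study())
        assert np.allclose(records["dice"], 1.0)
        assert np.allclose(records["hausdorff_mm"], 0.0)

    def test_record_count_bookkeeping(self):
        bundle = make_study(n_lesions=2, n_observers=3, seed=4)
        records = compute_iov({l.lesion_id: l.delineations for l in bundle.lesions})
        assert len(records) == 2 * 3 * 2  # lesions x observers x modalities

    def test_mismatched_observers_across_modalities_rejected(self):
        study = self._unanimous_study()
        dset = study["lesion01"]["MRI"]
        study["lesion01"]["MRI"] = cs.ObserverDelineationSet(
            entries=[("other1", dset.masks[0]), ("other2", dset.masks[1])],
            lesion_id="lesion01",
        )
        with pytest.raises(ValueError, match="observers differ"):
            compute_iov(study)


class TestCompareModalities:
    def test_hand_worked_signed_ranks_n8(self):
        """d = (1.5, -0.5, 2.5, 3, -1, 4, 0.75, -2): |d| ranks are
        (4,1,6,7,3,8,2,5) so W+ = 4+6+7+8+2 = 27, W- = 1+3+5 = 9."""
        a = np.array([2.0, 1.0, 3.5, 4.0, 1.0, 5.0, 1.75, 0.5])
        b = a - np.array([1.5, -0.5, 2.5, 3.0, -1.0, 4.0, 0.75, -2.0])
        records = _records_from_pairs(a, b)
        rep = compare_modalities(records, "dice")
        assert rep.n_pairs == 8
        assert rep.statistic in (9.0, 27.0)  # min-rank-sum convention either way
        assert rep.p_value == pytest.approx(exact_wilcoxon_p(a - b))

    def test_exact_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        for n in (6, 9, 12):
            d = rng.normal(0.3, 1.0, n)
            d[d == 0] = 0.1
            rep = compare_modalities(_records_from_pairs(d, np.zeros(n)), "dice")
            assert rep.p_value == pytest.approx(exact_wilcoxon_p(d), abs=1e-12)

    def test_identical_samples_degenerate(self):
        vals = np.linspace(0.5, 0.9, 6)
        with pytest.raises(ValueError, match="zero"):
            compare_modalities(_records_from_pairs(vals, vals), "dice")

    def test_invariant_to_record_ordering(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(12), rng.random(12)
        records = _records_from_pairs(a, b)
        shuffled = records.sample(frac=1, random_state=0).reset_index(drop=True)
        r1 = compare_modalities(records, "dice")
        r2 = compare_modalities(shuffled, "dice")
        assert (r1.statistic, r1.p_value) == (r2.statistic, r2.p_value)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(9)
        a, b = rng.random(60), rng.random(60)
        rep = compare_modalities(_records_from_pairs(a, b), "dice")
        assert 0 <= rep.p_value <= 1
        assert rep.n_pairs == 60


class TestCorrelation:
    def test_perfect_monotone_is_plus_one(self):
        t = np.array([10.0, 12.0, 15.0, 18.0, 25.0])
        rep = correlate_threshold_volume(t, t**2)
        assert rep.spearman_rho == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        t = np.array([10.0, 12.0, 15.0, 18.0, 25.0])
        rep = correlate_threshold_volume(t, -t)
        assert rep.spearman_rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(14)
        x, y = rng.random(10), rng.random(10)
        rep = correlate_threshold_volume(x, y)
        assert rep.spearman_rho == pytest.approx(spearman_rho_oracle(x, y), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate_threshold_volume([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPlantedEffectDirection:
    def test_tighter_pet_errors_raise_pet_dice(self):
        """With a smaller PET-condition error scale, the PET condition's mean
        Dice exceeds the anatomical-only condition's in every seeded study."""
        wins = 0
        n_seeds = 3
        for seed in range(n_seeds):
            bundle = make_study(
                n_lesions=3, n_observers=4,
                grid=ImageGrid((40, 40, 24), (4.0, 4.0, 5.0)),
                seed=100 + seed,
            )
            records = compute_iov(
                {l.lesion_id: l.delineations for l in bundle.lesions}
            )
            means = records.groupby("modality")["dice"].mean()
            wins += means["MRI_PET"] > means["MRI"]
        assert wins == n_seeds


class TestStudyDriver:
    def test_end_to_end_outputs_and_determinism(self, tmp_path):
        config = {
            "synthetic": {"n_lesions": 2, "n_observers": 3, "seed": 5},
            "validation": {"n_lesions": 2, "n_observers": 3, "seed": 6},
        }
        out1, out2 = tmp_path / "run1", tmp_path / "run2"
        rep1 = cs.run_study(config, outdir=out1)
        rep2 = cs.run_study(config, outdir=out2)
        for name in ("iov.csv", "sweep.csv", "validation.csv", "stats.json",
                     "manifest.json"):
            assert (out1 / name).exists(), name
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
        assert rep1.sweep_result.best_threshold == rep2.sweep_result.best_threshold
        assert set(rep1.iov_records["modality"]) == {"MRI", "MRI_PET"}

    def test_missing_pet_skips_sweep_with_notice(self, caplog):
        bundle = make_study(n_lesions=2, n_observers=3, seed=7)
        for lesion in bundle.lesions:
            lesion.pet = None
        with caplog.at_level("WARNING", logger="consenseg"):
            report = IOVStudy(bundle).fit()
        assert report.sweep_result is None
        assert any("skipping the threshold sweep" in m for m in caplog.messages)
        assert not report.iov_records.empty
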