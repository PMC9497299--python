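"""Inter-observer variability study: consensus, metrics, paired statistics.

The study design this orchestrates: every lesion is contoured by the same
observers under two modality conditions (anatomical imaging only, "MRI",
and with functional PET added, "MRI_PET"). Per lesion and condition a
STAPLE consensus is built from that condition's contours only, and each
observer is scored against their own condition's consensus (Dice, Hausdorff,
volume). Conditions are then compared by a two-sided Wilcoxon signed-rank
test paired on (lesion x observer); the threshold-vs-volume relationship is
probed with Spearman's rank correlation. Alpha is 0.05 throughout, raw
(uncorrected) p-values.

Statistical conventions: zero paired differences are dropped (Wilcoxon's
original treatment); the exact signed-rank null is used for n <= 25 and the
normal approximation with continuity correction above; lesions of one
patient are treated as independent (a caveat for real cohorts, exact for
the synthetic generator which draws lesions independently).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import dice, hausdorff, mask_volume
from .staple import StapleModel
from .threshold import ThresholdSweep, evaluate_on_validation, roi_from_masks

__all__ = [
    "IOVRecord",
    "StatsReport",
    "compute_iov",
    "compare_modalities",
    "correlate_threshold_volume",
    "IOVStudy",
    "StudyReport",
    "run_study",
]

logger = logging.getLogger("consenseg")

EXACT_WILCOXON_MAX_N = 25
ALPHA = 0.05


@dataclass(frozen=True)
class IOVRecord:
    """One observer contour scored against its condition's consensus."""

    lesion_id: str
    observer_id: str
    modality: str
    dice: float
    hausdorff_mm: float
    volume_cm3: float
    consensus_volume_cm3: float


@dataclass(frozen=True)
class StatsReport:
    """Outcome of one paired test or correlation."""

    paired_metric: str
    n_pairs: int
    statistic: float
    p_value: float
    alpha: float = ALPHA
    spearman_rho: float | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def compute_iov(delineations_by_lesion, consensus_cutoff: float = 0.5,
                staple_kwargs: dict | None = None) -> pd.DataFrame:
    """Score every observer against the per-(lesion, modality) consensus.

    Parameters
    ----------
    delineations_by_lesion
        Mapping ``lesion_id -> {modality -> ObserverDelineationSet}``; each
        lesion must carry the same observers in every modality.

    Returns
    -------
    DataFrame with one row per (lesion, observer, modality): the fields of
    :class:`IOVRecord`.
    """
    staple_kwargs = staple_kwargs or {}
    records = []
    for lesion_id, by_modality in delineations_by_lesion.items():
        observer_sets = {m: set(d.observer_ids) for m, d in by_modality.items()}
        if len(set(map(frozenset, observer_sets.values()))) != 1:
            raise ValueError(
                f"lesion {lesion_id!r}: observers differ across modalities "
                f"{observer_sets}"
            )
        for modality, dset in by_modality.items():
            result = StapleModel(dset, **staple_kwargs).fit()
            consensus = result.consensus_mask(cutoff=consensus_cutoff)
            cons_vol = mask_volume(consensus)
            for observer_id, mask in dset.entries:
                d = dice(mask, consensus)
                hd = (
                    float("nan")
                    if mask.is_empty() or consensus.is_empty()
                    else hausdorff(mask, consensus)
                )
                records.append(
                    IOVRecord(
                        lesion_id=lesion_id,
                        observer_id=observer_id,
                        modality=modality,
                        dice=d,
                        hausdorff_mm=hd,
                        volume_cm3=mask_volume(mask),
                        consensus_volume_cm3=cons_vol,
                    )
                )
    return pd.DataFrame([asdict(r) for r in records])


_METRIC_COLUMNS = {"dice": "dice", "hausdorff": "hausdorff_mm", "volume": "volume_cm3"}


def compare_modalities(records: pd.DataFrame, metric: str,
                       modalities: tuple = ("MRI", "MRI_PET")) -> StatsReport:
    """Two-sided Wilcoxon signed-rank test between the two conditions.

    Pairs are (lesion x observer); every pair must be present in both
    conditions. Zero differences are dropped; all-zero differences are a
    degeneracy error rather than p = 1.
    """
    if metric not in _METRIC_COLUMNS:
        raise ValueError(f"metric must be one of {sorted(_METRIC_COLUMNS)}")
    col = _METRIC_COLUMNS[metric]
    wide = records.pivot_table(
        index=["lesion_id", "observer_id"], columns="modality", values=col,
        aggfunc="first",
    )
    for m in modalities:
        if m not in wide.columns:
            raise ValueError(f"no records for modality {m!r}")
    wide = wide[list(modalities)].dropna()
    if wide.empty:
        raise ValueError("no complete (lesion, observer) pairs across both modalities")
    diffs = wide[modalities[0]].to_numpy() - wide[modalities[1]].to_numpy()
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        raise ValueError(
            "all paired differences are zero; the signed-rank test is degenerate"
        )
    method = "exact" if nonzero.size <= EXACT_WILCOXON_MAX_N else "approx"
    res = stats.wilcoxon(
        nonzero, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return StatsReport(
        paired_metric=metric,
        n_pairs=int(nonzero.size),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def correlate_threshold_volume(per_lesion_best, volumes) -> StatsReport:
    """Spearman rank correlation between per-lesion optimal thresholds and
    the corresponding consensus volumes (average ranks for ties, two-sided p).
    """
    t = np.asarray(per_lesion_best, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if t.shape != v.shape:
        raise ValueError("threshold and volume vectors must be aligned")
    if t.size < 3:
        raise ValueError("need at least 3 lesions for a rank correlation")
    if np.all(t == t[0]) or np.all(v == v[0]):
        raise ValueError("constant input vector; Spearman rho is undefined")
    rho, p = stats.spearmanr(t, v)
    return StatsReport(
        paired_metric="threshold_vs_volume",
        n_pairs=int(t.size),
        statistic=float(rho),
        p_value=float(p),
        spearman_rho=float(rho),
    )


# ---------------------------------------------------------------------------
# End-to-end study driver


@dataclass
class StudyReport:
    """Everything :class:`IOVStudy` computes, plus provenance."""

    iov_records: pd.DataFrame
    stats: dict  # metric -> StatsReport (+ correlation)
    sweep_result: object | None  # ThresholdSweepResult when PET present
    validation_metrics: pd.DataFrame | None
    manifest: dict

    def summary(self) -> str:
        lines = ["Inter-observer variability study", "=" * 40]
        for modality, sub in self.iov_records.groupby("modality"):
            lines.append(
                f"  {modality:<8} dice {sub['dice'].mean():.3f} ± {sub['dice'].std():.3f}"
                f"   hausdorff {sub['hausdorff_mm'].mean():6.2f} ± "
                f"{sub['hausdorff_mm'].std():.2f} mm"
                f"   volume {sub['volume_cm3'].mean():6.2f} cm^3"
            )
        for name, rep in self.stats.items():
            if rep is None:
                continue
            lines.append(
                f"  {name:<22} n={rep.n_pairs:<4} stat={rep.statistic:10.4f} "
                f"p={rep.p_value:.4g}{' *' if rep.significant else ''}"
            )
        if self.sweep_result is not None:
            lines.append(
                f"  best threshold: {self.sweep_result.best_threshold:g}% of SUVmax "
                f"(mean Dice {self.sweep_result.best_mean_dice:.3f})"
            )
        if self.validation_metrics is not None:
            vm = self.validation_metrics
            lines.append(
                f"  validation: dice {vm['dice'].mean():.3f} ± {vm['dice'].std():.3f} "
                f"over {len(vm)} lesions"
            )
        return "\n".join(lines)

    def write(self, outdir):
        """Write iov.csv, sweep.csv, validation.csv, stats.json, manifest.json."""
        import os

        os.makedirs(outdir, exist_ok=True)
        self.iov_records.to_csv(os.path.join(outdir, "iov.csv"), index=False)
        stats_json = {
            name: (asdict(rep) if rep is not None else None)
            for name, rep in self.stats.items()
        }
        if self.sweep_result is not None:
            self.sweep_result.to_frame().to_csv(
                os.path.join(outdir, "sweep.csv"), index=False
            )
            stats_json["threshold_sweep"] = {
                "best_threshold_pct": self.sweep_result.best_threshold,
                "best_mean_dice": self.sweep_result.best_mean_dice,
                "per_lesion_best": {
                    str(k): float(v)
                    for k, v in self.sweep_result.per_lesion_best.items()
                },
            }
        if self.validation_metrics is not None:
            self.validation_metrics.to_csv(
                os.path.join(outdir, "validation.csv"), index=False
            )
        with open(os.path.join(outdir, "stats.json"), "w") as fh:
            json.dump(stats_json, fh, indent=2)
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


class IOVStudy:
    """Statsmodels-style driver: build from a study bundle, ``fit()`` to run.

    Parameters
    ----------
    bundle
        A :class:`consenseg.simulate.StudyBundle` (or anything exposing
        ``lesions`` with ``lesion_id``, ``pet``, ``delineations``), the
        tuning cohort.
    validation_bundle
        Optional independent cohort for evaluating the tuned threshold.
    sweep_modality
        Condition whose consensus serves as the threshold-sweep reference.
    """

    def __init__(
        self,
        bundle,
        validation_bundle=None,
        sweep_modality: str = "MRI_PET",
        consensus_cutoff: float = 0.5,
        clip_to_roi: bool = False,
        roi_pad: int = 3,
        staple_kwargs: dict | None = None,
    ):
        self.bundle = bundle
        self.validation_bundle = validation_bundle
        self.sweep_modality = sweep_modality
        self.consensus_cutoff = consensus_cutoff
        self.clip_to_roi = clip_to_roi
        self.roi_pad = roi_pad
        self.staple_kwargs = staple_kwargs or {}

    def fit(self, run_sweep: bool = True) -> StudyReport:
        delineations = {
            l.lesion_id: l.delineations for l in self.bundle.lesions
        }
        logger.info("computing IOV records for %d lesions", len(delineations))
        records = compute_iov(
            delineations,
            consensus_cutoff=self.consensus_cutoff,
            staple_kwargs=self.staple_kwargs,
        )
        stats_out = {}
        modalities = sorted(records["modality"].unique())
        if len(modalities) >= 2:
            for metric in ("dice", "hausdorff", "volume"):
                try:
                    stats_out[f"wilcoxon_{metric}"] = compare_modalities(
                        records, metric, modalities=tuple(modalities[:2])
                    )
                except ValueError as e:
                    logger.warning("wilcoxon on %s skipped: %s", metric, e)
                    stats_out[f"wilcoxon_{metric}"] = None

        sweep_result = None
        validation_metrics = None
        have_pet = all(l.pet is not None for l in self.bundle.lesions)
        if run_sweep and have_pet:
            sweep_result = self._run_sweep(records)
            cons_vol = (
                records.query("modality == @self.sweep_modality")
                .groupby("lesion_id")["consensus_volume_cm3"]
                .first()
            )
            aligned = cons_vol.reindex(sweep_result.per_lesion_best.index)
            try:
                stats_out["spearman_threshold_volume"] = correlate_threshold_volume(
                    sweep_result.per_lesion_best.to_numpy(), aligned.to_numpy()
                )
            except ValueError as e:
                logger.warning("spearman skipped: %s", e)
                stats_out["spearman_threshold_volume"] = None
            if self.validation_bundle is not None:
                validation_metrics = self._run_validation(sweep_result.best_threshold)
        elif run_sweep and not have_pet:
            logger.warning("PET volumes missing; skipping the threshold sweep")

        manifest = {
            "n_lesions": len(self.bundle.lesions),
            "modalities": modalities,
            "consensus_cutoff": self.consensus_cutoff,
            "clip_to_roi": self.clip_to_roi,
            "roi_pad": self.roi_pad,
            "sweep_modality": self.sweep_modality,
            "bundle_manifest": getattr(self.bundle, "manifest", None),
        }
        return StudyReport(
            iov_records=records,
            stats=stats_out,
            sweep_result=sweep_result,
            validation_metrics=validation_metrics,
            manifest=manifest,
        )

    # -- helpers ----------------------------------------------------------

    def _consensus_for(self, lesion, modality):
        dset = lesion.delineations[modality]
        return (
            StapleModel(dset, **self.staple_kwargs)
            .fit()
            .consensus_mask(cutoff=self.consensus_cutoff)
        )

    def _sweep_items(self, bundle, modality):
        items, refs = [], []
        for lesion in bundle.lesions:
            dset = lesion.delineations[modality]
            roi = roi_from_masks(
                dset.masks, lesion_id=lesion.lesion_id, pad=self.roi_pad
            )
            items.append((lesion.lesion_id, lesion.pet, roi))
            refs.append(self._consensus_for(lesion, modality))
        return items, refs

    def _run_sweep(self, records):
        items, refs = self._sweep_items(self.bundle, self.sweep_modality)
        lesions = [(lid, pet, roi, ref) for (lid, pet, roi), ref in zip(items, refs)]
        logger.info("sweeping thresholds over %d lesions", len(lesions))
        return ThresholdSweep(lesions, clip_to_roi=self.clip_to_roi).fit()

    def _run_validation(self, threshold):
        modality = self.sweep_modality
        vb = self.validation_bundle
        if not all(modality in l.delineations for l in vb.lesions):
            # validation contours may exist only for the PET-assisted setting
            modality = next(iter(vb.lesions[0].delineations))
        items, refs = self._sweep_items(vb, modality)
        logger.info(
            "validating threshold %.1f%% on %d lesions", threshold, len(items)
        )
        return evaluate_on_validation(
            threshold, items, refs, clip_to_roi=self.clip_to_roi
        )


def run_study(config, outdir=None) -> StudyReport:
    """Run the full pipeline from a config mapping or YAML path.

    The config either describes a synthetic study (``synthetic:`` section
    passed to :func:`consenseg.simulate.make_study`, optionally
    ``validation:`` for the independent cohort) or lists NIfTI files per
    lesion/observer/modality (``lesions:`` section; ``pet`` optional —
    without it the sweep is skipped with a notice).
    """
    import yaml

    if isinstance(config, (str, bytes)) or hasattr(config, "read"):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)

    if "synthetic" in config:
        from .simulate import make_study

        bundle = make_study(**config["synthetic"])
        validation = (
            make_study(**config["validation"]) if "validation" in config else None
        )
    elif "lesions" in config:
        bundle = _bundle_from_files(config["lesions"])
        validation = (
            _bundle_from_files(config["validation_lesions"])
            if "validation_lesions" in config
            else None
        )
    else:
        raise ValueError("config needs a 'synthetic' or 'lesions' section")

    study = IOVStudy(
        bundle,
        validation_bundle=validation,
        sweep_modality=config.get("sweep_modality", "MRI_PET"),
        consensus_cutoff=config.get("consensus_cutoff", 0.5),
        clip_to_roi=config.get("clip_to_roi", False),
        roi_pad=config.get("roi_pad", 3),
    )
    report = study.fit(run_sweep=config.get("run_sweep", True))
    report.manifest["config"] = {
        k: v for k, v in config.items() if k not in ("lesions", "validation_lesions")
    }
    if outdir is not None:
        report.write(outdir)
    return report


def _bundle_from_files(lesion_cfgs):
    """Assemble a study bundle from a config listing NIfTI paths."""
    from .io import read_mask, read_volume
    from .simulate import StudyBundle, StudyLesion
    from .staple import ObserverDelineationSet

    lesions = []
    for cfg in lesion_cfgs:
        lesion_id = cfg["id"]
        pet = read_volume(cfg["pet"]) if "pet" in cfg else None
        delineations = {}
        for modality, by_observer in cfg["masks"].items():
            entries = [
                (observer_id, read_mask(path, threshold_nonbinary=True))
                for observer_id, path in sorted(by_observer.items())
            ]
            delineations[modality] = ObserverDelineationSet(
                entries=entries, lesion_id=lesion_id, modality=modality
            )
        lesions.append(
            StudyLesion(
                lesion_id=lesion_id, truth=None, pet=pet, delineations=delineations
            )
        )
    return StudyBundle(lesions=lesions, manifest={"source": "files"})


def _configure_logging(verbose: bool = True):
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
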