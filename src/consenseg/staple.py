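"""Binary STAPLE: EM consensus of multiple delineations.

STAPLE (simultaneous truth and performance level estimation) treats the
unknown true segmentation ``T`` as a latent binary field and each observer
``j`` as a noisy channel with sensitivity ``p_j = P(D_j=1 | T=1)`` and
specificity ``q_j = P(D_j=0 | T=0)``. Expectation-maximization alternates:

E-step, per voxel ``i`` with decisions ``D_ij``::

    a_i = γ · Π_j p_j^D_ij (1-p_j)^(1-D_ij)
    b_i = (1-γ) · Π_j (1-q_j)^D_ij q_j^(1-D_ij)
    W_i = a_i / (a_i + b_i)

M-step::

    p_j = Σ_i W_i D_ij / Σ_i W_i
    q_j = Σ_i (1-W_i)(1-D_ij) / Σ_i (1-W_i)

The foreground prior ``γ`` is held fixed during EM — by default at the mean
observer occupancy fraction, the common published choice. This is the
spatially unregularized binary STAPLE; MRF-regularized and multi-label
variants are non-goals.

Numerical notes
---------------
* The E-step runs in log space; ``p_j``/``q_j`` are clipped to
  ``[1e-12, 1-1e-12]`` so unanimous raters converge to 1 without NaNs.
* Computation is restricted to the bounding box of the union of the input
  masks, padded by ``bbox_margin`` voxels; outside voxels are unanimous
  background (weight 0) and are excluded from ``γ`` and the M-step sums.
  Without this restriction the overwhelming empty background would drive
  ``γ`` toward 0 on whole head volumes.
* The observed-data log-likelihood ``Σ_i log(a_i + b_i)`` is recorded per
  iteration; EM guarantees it is non-decreasing, which the test suite
  asserts on every trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import BinaryMask, ImageGrid, assert_same_grid

__all__ = [
    "ObserverDelineationSet",
    "StapleModel",
    "StapleResult",
    "run_staple",
    "consensus_mask",
]

_EPS = 1e-12


@dataclass
class ObserverDelineationSet:
    """Delineations of one lesion by several observers, on one shared grid."""

    entries: list  # list of (observer_id, BinaryMask)
    lesion_id: str = "lesion"
    modality: str = "MRI"

    def __post_init__(self):
        if len(self.entries) < 2:
            raise ValueError("need at least 2 observers")
        ids = [oid for oid, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError(f"observer ids must be unique, got {ids}")
        assert_same_grid([m for _, m in self.entries])

    @property
    def observer_ids(self):
        return [oid for oid, _ in self.entries]

    @property
    def masks(self):
        return [m for _, m in self.entries]

    @property
    def grid(self) -> ImageGrid:
        return self.entries[0][1].grid

    @classmethod
    def from_masks(cls, masks, lesion_id="lesion", modality="MRI"):
        entries = [(f"obs{j + 1}", m) for j, m in enumerate(masks)]
        return cls(entries=entries, lesion_id=lesion_id, modality=modality)


@dataclass
class StapleResult:
    """Fitted consensus: posterior weight map plus per-observer performance."""

    grid: ImageGrid
    weights: np.ndarray  # P(T_i = 1 | D) per voxel, full grid
    observer_ids: list
    sensitivity: np.ndarray  # p_j
    specificity: np.ndarray  # q_j
    prior: float  # γ, P(T=1), fixed during EM
    n_iterations: int
    converged: bool
    trace: np.ndarray  # per-iteration relative change of Σ W_i
    loglik_trace: np.ndarray = field(default=None)

    def consensus_mask(self, cutoff: float = 0.5) -> BinaryMask:
        """Threshold the weight map; voxels with W_i >= cutoff are occupied."""
        if not 0 < cutoff < 1:
            raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
        return BinaryMask(self.grid, self.weights >= cutoff)

    def performance_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "observer_id": self.observer_ids,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )

    def summary(self) -> str:
        lines = [
            "STAPLE consensus (binary, unregularized)",
            f"  observers      : {len(self.observer_ids)}",
            f"  prior gamma    : {self.prior:.6f}",
            f"  iterations     : {self.n_iterations} "
            f"({'converged' if self.converged else 'NOT converged'})",
            f"  consensus vox  : {int(np.count_nonzero(self.weights >= 0.5))}",
            "  observer   sensitivity p  specificity q",
        ]
        for oid, p, q in zip(self.observer_ids, self.sensitivity, self.specificity):
            lines.append(f"  {oid:<10} {p:13.6f}  {q:13.6f}")
        return "\n".join(lines)

    def to_report(self) -> dict:
        return {
            "observers": list(self.observer_ids),
            "sensitivity": [float(x) for x in self.sensitivity],
            "specificity": [float(x) for x in self.specificity],
            "prior": float(self.prior),
            "n_iterations": int(self.n_iterations),
            "converged": bool(self.converged),
        }


class StapleModel:
    """Binary STAPLE model for one set of observer delineations.

    Parameters
    ----------
    delineations
        An :class:`ObserverDelineationSet`, or a plain list of
        :class:`BinaryMask` (observer ids are auto-assigned).
    init_sensitivity, init_specificity
        EM starting values for every observer, strictly inside (0, 1).
        0.9/0.9 is standard practice and avoids the absorbing state at 1.
    prior_mode
        ``"mean_occupancy"`` (default): γ is the mean occupied fraction over
        observers, computed on the restricted region. ``"fixed"``: use
        ``fixed_prior``. γ is not updated during EM.
    bbox_margin
        Padding (voxels) around the union bounding box inside which EM runs.
    """

    def __init__(
        self,
        delineations,
        init_sensitivity: float = 0.9,
        init_specificity: float = 0.9,
        prior_mode: str = "mean_occupancy",
        fixed_prior: float | None = None,
        bbox_margin: int = 5,
    ):
        if not isinstance(delineations, ObserverDelineationSet):
            delineations = ObserverDelineationSet.from_masks(list(delineations))
        if not (0 < init_sensitivity < 1 and 0 < init_specificity < 1):
            raise ValueError("initial sensitivity/specificity must lie strictly in (0, 1)")
        if prior_mode not in ("mean_occupancy", "fixed"):
            raise ValueError(f"unknown prior_mode {prior_mode!r}")
        if prior_mode == "fixed":
            if fixed_prior is None or not 0 < fixed_prior < 1:
                raise ValueError("prior_mode='fixed' needs fixed_prior in (0, 1)")
        self.delineations = delineations
        self.init_sensitivity = float(init_sensitivity)
        self.init_specificity = float(init_specificity)
        self.prior_mode = prior_mode
        self.fixed_prior = fixed_prior
        self.bbox_margin = int(bbox_margin)

    # -- internals --------------------------------------------------------

    def _region_slices(self):
        union = np.zeros(self.delineations.grid.shape, dtype=bool)
        for m in self.delineations.masks:
            union |= m.values
        if not union.any():
            raise ValueError("all observer masks are empty; STAPLE is undefined")
        idx = np.argwhere(union)
        lo = np.maximum(idx.min(axis=0) - self.bbox_margin, 0)
        hi = np.minimum(idx.max(axis=0) + self.bbox_margin + 1, union.shape)
        return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))

    def fit(self, tol: float = 1e-6, max_iter: int = 100) -> StapleResult:
        """Run EM to convergence (relative change of Σ W_i below ``tol``)."""
        if tol <= 0:
            raise ValueError("tol must be > 0")
        if max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        dset = self.delineations
        region = self._region_slices()
        # decisions: (J, N) over the restricted region
        D = np.stack([m.values[region].ravel() for m in dset.masks]).astype(float)
        J, N = D.shape

        if self.prior_mode == "fixed":
            gamma = float(self.fixed_prior)
        else:
            gamma = float(D.mean())
        gamma = min(max(gamma, _EPS), 1 - _EPS)

        p = np.full(J, self.init_sensitivity)
        q = np.full(J, self.init_specificity)

        log_gamma = np.log(gamma)
        log_1m_gamma = np.log1p(-gamma)

        W = None
        prev_sum_w = None
        rel_changes = []
        logliks = []
        converged = False
        n_iter = 0
        for _ in range(max_iter):
            n_iter += 1
            pc = np.clip(p, _EPS, 1 - _EPS)
            qc = np.clip(q, _EPS, 1 - _EPS)
            # E-step in log space: (J,1) broadcast against (J,N)
            log_a = log_gamma + (
                D * np.log(pc)[:, None] + (1 - D) * np.log1p(-pc)[:, None]
            ).sum(axis=0)
            log_b = log_1m_gamma + (
                D * np.log1p(-qc)[:, None] + (1 - D) * np.log(qc)[:, None]
            ).sum(axis=0)
            logliks.append(float(np.logaddexp(log_a, log_b).sum()))
            with np.errstate(over="ignore"):
                W = 1.0 / (1.0 + np.exp(log_b - log_a))

            sum_w = float(W.sum())
            sum_not_w = float(N - sum_w)
            if sum_w <= 0:
                raise ArithmeticError(
                    "EM collapsed: total foreground weight is zero (Σ W_i = 0)"
                )
            if sum_not_w <= 0:
                raise ArithmeticError(
                    "EM collapsed: total background weight is zero (Σ (1-W_i) = 0)"
                )
            if prev_sum_w is not None:
                rel = abs(sum_w - prev_sum_w) / prev_sum_w
                rel_changes.append(rel)
                if rel < tol:
                    converged = True
                    break
            prev_sum_w = sum_w

            # M-step
            p = (W[None, :] * D).sum(axis=1) / sum_w
            q = ((1 - W)[None, :] * (1 - D)).sum(axis=1) / sum_not_w

        weights = np.zeros(dset.grid.shape, dtype=float)
        weights[region] = W.reshape(tuple(s.stop - s.start for s in region))
        return StapleResult(
            grid=dset.grid,
            weights=weights,
            observer_ids=list(dset.observer_ids),
            sensitivity=np.asarray(p, dtype=float),
            specificity=np.asarray(q, dtype=float),
            prior=gamma,
            n_iterations=n_iter,
            converged=converged,
            trace=np.asarray(rel_changes),
            loglik_trace=np.asarray(logliks),
        )


def run_staple(
    observers,
    init_sensitivity: float = 0.9,
    init_specificity: float = 0.9,
    prior_mode: str = "mean_occupancy",
    fixed_prior: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    bbox_margin: int = 5,
) -> StapleResult:
    """Functional one-shot wrapper around :class:`StapleModel`."""
    model = StapleModel(
        observers,
        init_sensitivity=init_sensitivity,
        init_specificity=init_specificity,
        prior_mode=prior_mode,
        fixed_prior=fixed_prior,
        bbox_margin=bbox_margin,
    )
    return model.fit(tol=tol, max_iter=max_iter)


def consensus_mask(result: StapleResult, cutoff: float = 0.5) -> BinaryMask:
    """Extract the consensus delineation from a fitted STAPLE result."""
    return result.consensus_mask(cutoff=cutoff)
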