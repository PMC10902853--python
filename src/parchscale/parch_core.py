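"""The parch statistic: monotonized water counts, autocorrelation, parch values.

The pipeline per residue i:

1. ``monotonize`` imposes a monotonicity condition on the raw water-count
   series w_i(t): eta_i(t) = min_{s<=t} w_i(s), the running minimum. As the
   annealing temperature only rises, genuine rehydration cannot occur and
   upward fluctuations are counting noise; eta is the largest non-increasing
   series bounded above by w.
2. ``autocorrelation`` forms the lag autocorrelation
   C_i(tau) = (1/(T-tau)) * sum_t eta_i(t) eta_i(t+tau), normalized to
   C_i(0) = 1 (an all-zero eta gives C identically 0).
3. ``average_acf`` takes the time integral of C_i over lags, divided by the
   maximum lag: Cbar_i = (1/tau_max) * integral_0^tau_max C_i(tau) d tau
   (trapezoid rule). Cbar is a dimensionless mean in [0, 1] for normalized
   ACFs: 1 when no water is ever lost, smaller the earlier water departs.
4. ``parch_value`` scales by a reference residue:
   PV_i = 10 * Cbar_i / Cbar_ref. A residue retaining water like the
   reference (lysine, in the original calibration) scores 10; a residue
   that never sees water scores 0.

Each stage sits behind a named strategy registry so alternative concrete
forms can be swapped without touching callers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .hydration_counter import WaterCountSeries

__all__ = [
    "ParchParams",
    "ParchResult",
    "monotonize",
    "autocorrelation",
    "average_acf",
    "parch_value",
    "reference_cbar_from_series",
    "compute_parch",
    "categorize",
    "categorize_and_summarize",
    "heatmap_bins",
    "PARCH_SCALE",
    "CATEGORY_EDGES",
]

#: the fixed expansion factor applied to the Cbar ratio
PARCH_SCALE = 10.0

#: category cutpoints: low [0, 0.1], medium (0.1, 0.8], high (0.8, inf)
CATEGORY_EDGES = (0.1, 0.8)

STANDARD_AA_ORDER = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()


# ---------------------------------------------------------------------------
# stage strategies

def _running_minimum(w: np.ndarray) -> np.ndarray:
    return np.minimum.accumulate(w)


MONOTONIZE_STRATEGIES: dict[str, Callable] = {"running-min": _running_minimum}


def _lag_mean_product_acf(eta: np.ndarray, normalize: bool) -> np.ndarray:
    T = eta.size
    raw = np.correlate(eta, eta, mode="full")[T - 1:]
    C = raw / (T - np.arange(T))
    if normalize:
        if C[0] == 0:
            return np.zeros(T)
        C = C / C[0]
    return C


ACF_STRATEGIES: dict[str, Callable] = {"lag-mean-product": _lag_mean_product_acf}


def _trapezoid_mean(C: np.ndarray, dt: float) -> float:
    tau_max = (C.size - 1) * dt
    return float(np.trapezoid(C, dx=dt) / tau_max)


INTEGRAL_STRATEGIES: dict[str, Callable] = {"trapezoid": _trapezoid_mean}


# ---------------------------------------------------------------------------
# public operations

def monotonize(w, strategy: str = "running-min") -> np.ndarray:
    """Impose the monotonicity condition: eta(t) = min over s <= t of w(s).

    eta is non-increasing, pointwise <= w, and equals w exactly when w is
    already non-increasing. Raises on negative counts.
    """
    w = np.asarray(w, dtype=float)
    if w.size == 0:
        raise ValueError("water-count series is empty")
    if np.any(w < 0):
        raise ValueError("water counts must be non-negative")
    return MONOTONIZE_STRATEGIES[strategy](w)


def autocorrelation(eta, normalize: bool = True, strategy: str = "lag-mean-product") -> np.ndarray:
    """Lag autocorrelation C(tau) of a monotonized count series.

    C(tau) = (1/(T-tau)) sum_{t=0}^{T-tau-1} eta(t) eta(t+tau), sampled at
    every frame lag tau = 0..T-1. With `normalize`, C is divided by C(0)
    so C(0) = 1; an all-zero series returns C identically 0 rather than
    dividing by zero.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.size < 2:
        raise ValueError("autocorrelation needs at least 2 samples")
    return ACF_STRATEGIES[strategy](eta, normalize)


def average_acf(C, dt: float, strategy: str = "trapezoid") -> float:
    """Length-normalized time integral Cbar = (1/tau_max) * int C(tau) d tau.

    The 1/tau_max normalization makes Cbar a dimensionless mean, so parch
    ratios compare trajectories of matched length without a unit factor.
    """
    C = np.asarray(C, dtype=float)
    if C.size < 2 or dt <= 0:
        raise ValueError("average_acf needs >= 2 lags and positive dt (tau_max > 0)")
    return INTEGRAL_STRATEGIES[strategy](C, dt)


def parch_value(cbar: float, cbar_ref: float) -> float:
    """PV = 10 * cbar / cbar_ref; 10 = reference-like retention, 0 = no water."""
    if cbar_ref <= 0:
        raise ValueError("reference Cbar must be positive")
    if cbar < 0:
        raise ValueError("Cbar must be non-negative")
    pv = PARCH_SCALE * cbar / cbar_ref
    if pv > PARCH_SCALE:
        warnings.warn(
            f"parch value {pv:.3f} exceeds 10: the residue retains water "
            "longer than the chosen reference"
        )
    return pv


def categorize(pv: float) -> str:
    """Three-way split: low [0, 0.1], medium (0.1, 0.8], high (0.8, inf)."""
    lo, hi = CATEGORY_EDGES
    if pv <= lo:
        return "low"
    if pv <= hi:
        return "medium"
    return "high"


def _series_cbar(counts_row: np.ndarray, dt: float, params: "ParchParams") -> float:
    eta = monotonize(counts_row, strategy=params.monotonize_strategy)
    C = autocorrelation(eta, normalize=params.normalize_acf, strategy=params.acf_strategy)
    return average_acf(C, dt, strategy=params.integration)


@dataclass
class ParchParams:
    """Parameters of the parch computation.

    reference_cbar : the reference residue's Cbar (a positive number), or a
        single-residue :class:`WaterCountSeries` from which it is computed.
    normalize_acf : normalize the autocorrelation at lag 0 (default on);
        without it the statistic scales with the square of the water count.
    replicate_policy : "mean-of-Cbar" averages Cbar across replicates before
        the reference ratio; "mean-of-PV" averages the scaled values (the
        two commute when all replicates share one reference).
    """

    reference_cbar: Union[float, WaterCountSeries, None] = None
    scale: float = PARCH_SCALE
    normalize_acf: bool = True
    integration: str = "trapezoid"
    replicate_policy: str = "mean-of-Cbar"
    monotonize_strategy: str = "running-min"
    acf_strategy: str = "lag-mean-product"

    def __post_init__(self):
        if self.replicate_policy not in ("mean-of-Cbar", "mean-of-PV"):
            raise ValueError("replicate_policy must be 'mean-of-Cbar' or 'mean-of-PV'")
        if isinstance(self.reference_cbar, (int, float)) and self.reference_cbar <= 0:
            raise ValueError("reference_cbar must be positive")

    def resolve_reference(self) -> float:
        if self.reference_cbar is None:
            raise ValueError("a reference (Cbar value or single-residue series) is required")
        if isinstance(self.reference_cbar, WaterCountSeries):
            return reference_cbar_from_series(self.reference_cbar, self)
        return float(self.reference_cbar)


@dataclass
class ParchResult:
    """Per-residue parch outputs plus the global reference."""

    residue_labels: list[str]
    eta: np.ndarray  # (n_replicates, n_residues, n_frames)
    cbar: np.ndarray  # (n_residues,) replicate-aggregated
    parch_values: np.ndarray  # (n_residues,)
    categories: list[str]
    cbar_ref: float
    n_replicates: int
    residue_names: Optional[list[str]] = None

    def to_frame(self) -> pd.DataFrame:
        data = {
            "residue": self.residue_labels,
            "cbar": self.cbar,
            "parch_value": self.parch_values,
            "category": self.categories,
        }
        if self.residue_names is not None:
            data["resname"] = self.residue_names
        return pd.DataFrame(data)


def reference_cbar_from_series(series: WaterCountSeries,
                               params: Optional[ParchParams] = None) -> float:
    """Cbar of a single-residue reference system (e.g. a lone lysine).

    The series must contain exactly one residue and must not be all zero:
    a reference with no retained water cannot normalize anything.
    """
    params = params or ParchParams()
    if series.n_residues != 1:
        raise ValueError("reference series must contain exactly one residue")
    dt = float(series.times_ps[1] - series.times_ps[0]) if series.n_frames > 1 else None
    if dt is None:
        raise ValueError("reference series needs at least 2 frames")
    cbar = _series_cbar(series.counts[0], dt, params)
    if cbar <= 0:
        raise ValueError("reference series has zero Cbar (all-zero water counts?)")
    return cbar


def compute_parch(
    series: Union[WaterCountSeries, Sequence[WaterCountSeries]],
    params: Optional[ParchParams] = None,
) -> ParchResult:
    """Run the full parch pipeline on one count series or on replicates.

    Replicates must share the residue set and frame count. Per replicate,
    each residue's counts are monotonized, autocorrelated and
    time-averaged; Cbar (or PV, per the replicate policy) is then averaged
    across replicates and scaled against the reference.
    """
    params = params or ParchParams()
    replicates = [series] if isinstance(series, WaterCountSeries) else list(series)
    if not replicates:
        raise ValueError("no count series supplied")
    first = replicates[0]
    for rep in replicates[1:]:
        if rep.residue_labels != first.residue_labels:
            raise ValueError("replicates must share the residue set")
        if rep.n_frames != first.n_frames:
            raise ValueError("replicates must share the frame count")

    cbar_ref = params.resolve_reference()
    n_res, n_frames = first.counts.shape
    etas = np.zeros((len(replicates), n_res, n_frames))
    cbars = np.zeros((len(replicates), n_res))
    for r, rep in enumerate(replicates):
        dt = float(rep.times_ps[1] - rep.times_ps[0])
        for i in range(n_res):
            etas[r, i] = monotonize(rep.counts[i], strategy=params.monotonize_strategy)
            cbars[r, i] = _series_cbar(rep.counts[i], dt, params)

    if params.replicate_policy == "mean-of-Cbar":
        cbar = cbars.mean(axis=0)
        pvs = np.array([parch_value(c, cbar_ref) * (params.scale / PARCH_SCALE)
                        for c in cbar])
    else:
        pv_reps = np.array([[parch_value(c, cbar_ref) * (params.scale / PARCH_SCALE)
                             for c in row] for row in cbars])
        pvs = pv_reps.mean(axis=0)
        cbar = cbars.mean(axis=0)

    return ParchResult(
        residue_labels=list(first.residue_labels),
        eta=etas,
        cbar=cbar,
        parch_values=pvs,
        categories=[categorize(pv) for pv in pvs],
        cbar_ref=cbar_ref,
        n_replicates=len(replicates),
        residue_names=first.residue_names,
    )


# ---------------------------------------------------------------------------
# reporting

def categorize_and_summarize(result: ParchResult) -> pd.DataFrame:
    """Percentage of residues in the low/medium/high parch categories."""
    cats = pd.Series(result.categories)
    n = len(cats)
    rows = []
    for cat in ("low", "medium", "high"):
        count = int((cats == cat).sum())
        rows.append({"category": cat, "count": count, "percent": 100.0 * count / n})
    return pd.DataFrame(rows)


def heatmap_bins(
    results: Sequence[ParchResult],
    bin_width: float = 0.1,
    pv_max: float = 3.0,
) -> pd.DataFrame:
    """Residue-wise parch histogram: 20 amino acids x 0.1-wide bins over [0, 3].

    Rows are the 20 standard amino acids; columns are half-open bins
    [0, 0.1), [0.1, 0.2), ..., with the last regular bin closed at 3.0.
    Values above 3.0 land in an ">3.0" overflow column, with a warning.
    Matrix total equals the number of binned (standard) residues.
    """
    n_bins = int(round(pv_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    labels = [f"[{edges[i]:.1f},{edges[i + 1]:.1f})" for i in range(n_bins)]
    labels[-1] = f"[{edges[-2]:.1f},{edges[-1]:.1f}]"
    matrix = pd.DataFrame(0, index=STANDARD_AA_ORDER, columns=labels + [">3.0"])
    overflow = 0
    for result in results:
        if result.residue_names is None:
            raise ValueError("heatmap_bins needs residue names on every result")
        for name, pv in zip(result.residue_names, result.parch_values):
            name = name.upper()
            if name not in matrix.index:
                continue
            if pv > pv_max:
                matrix.loc[name, ">3.0"] += 1
                overflow += 1
            else:
                j = min(int(pv / bin_width), n_bins - 1)
                matrix.loc[name, labels[j]] += 1
    if overflow:
        warnings.warn(f"{overflow} residues exceed parch value {pv_max}; see overflow column")
    return matrix
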