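"""Ct quality control and conversion to relative quantities (RQ).

The preprocessing chain mirrors standard practice for serum/plasma miRNA
qPCR panels:

1. censor unreliable high-Ct calls (``Ct > threshold``, strict inequality);
2. flag extreme-low-Ct artifacts (threshold crossings that do not reflect
   real amplification) and apply user exclusion masks;
3. move to the linear scale: ``RQ = 2^-dCt`` with ``dCt = Ct_miRNA -
   Ct_spike`` against an exogenous spike-in, or against the overall
   highest-expressed (minimum mean Ct) detector when no common spike exists;
4. keep only detectors detected in at least a fraction (default 2/3) of the
   samples of *every* biological group;
5. impute the few remaining missing values by k-nearest-neighbour on the
   log2 scale;
6. append the three pseudo-detectors (per-sample arithmetic mean, geometric
   mean and median of RQs) that compete as candidate normalizers.

All operations return new objects and preserve detector and sample order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as qio
from .errors import ConfigError, DataError, InputError
from .io import CtMatrix, SampleAnnotation

log = logging.getLogger(__name__)

MODE_SPIKE = "spike"
MODE_MIN_CT = "min_ct"
MODE_UNKNOWN = "unknown"

PSEUDO_MEAN = "pseudo_mean"
PSEUDO_GEOMEAN = "pseudo_geomean"
PSEUDO_MEDIAN = "pseudo_median"
PSEUDO_IDS = (PSEUDO_MEAN, PSEUDO_GEOMEAN, PSEUDO_MEDIAN)


@dataclass
class RQMatrix:
    """Relative quantities on the linear scale.

    ``rq`` holds strictly positive values with ``NaN`` for missing cells.
    ``pseudo_flags`` marks the appended central-tendency rows; pseudo
    detectors are scored like candidates but are never used as the dCt
    reference nor counted in real-detector column sums.
    """

    rq: pd.DataFrame
    reference_mode: str = MODE_UNKNOWN
    reference_id: str = ""
    pseudo_flags: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.pseudo_flags is None:
            self.pseudo_flags = pd.Series(False, index=self.rq.index)
        if not self.pseudo_flags.index.equals(self.rq.index):
            raise InputError("pseudo_flags index must match rq detectors")
        if self.reference_mode not in (MODE_SPIKE, MODE_MIN_CT, MODE_UNKNOWN):
            raise InputError(f"unknown reference_mode {self.reference_mode!r}")
        vals = self.rq.to_numpy(dtype=float)
        present = np.isfinite(vals)
        if (vals[present] <= 0).any():
            raise InputError("present rq values must be strictly positive")
        if self.reference_id and self.reference_id in self.rq.index:
            if bool(self.pseudo_flags.get(self.reference_id, False)):
                raise InputError("a pseudo-detector cannot be the dCt reference")

    @property
    def detector_ids(self) -> list[str]:
        return list(self.rq.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rq.columns)

    @property
    def real_detector_ids(self) -> list[str]:
        return list(self.rq.index[~self.pseudo_flags])

    @property
    def real(self) -> pd.DataFrame:
        return self.rq.loc[~self.pseudo_flags]

    def is_complete(self) -> bool:
        return not self.rq.isna().to_numpy().any()

    def copy(self) -> "RQMatrix":
        return RQMatrix(
            self.rq.copy(), self.reference_mode, self.reference_id, self.pseudo_flags.copy()
        )

    def replace(self, rq: pd.DataFrame, pseudo_flags: pd.Series | None = None) -> "RQMatrix":
        flags = self.pseudo_flags if pseudo_flags is None else pseudo_flags
        return RQMatrix(rq, self.reference_mode, self.reference_id, flags.copy())


# ---------------------------------------------------------------------------
# Ct-level quality control
# ---------------------------------------------------------------------------

def censor_ct(ct: CtMatrix, threshold: float = 35.0) -> CtMatrix:
    """Censor observed cells with Ct strictly above ``threshold``.

    Values exactly at the threshold are kept (the rule is ``Ct > threshold``).
    """
    if threshold <= 0:
        raise InputError("threshold must be positive")
    out = ct.copy()
    mask = out.observed_mask() & (out.ct > threshold)
    out.ct[mask] = np.nan
    out.missing_reason[mask] = qio.REASON_ABOVE_THRESHOLD
    n = int(mask.to_numpy().sum())
    if n:
        log.info("censored %d cells with Ct > %g", n, threshold)
    return out


def flag_low_ct_outliers(ct: CtMatrix, floor: float = 10.0, exclude=None) -> CtMatrix:
    """Flag extreme-low-Ct cells as artifacts; apply a user exclusion mask.

    Abnormal amplification plots can cross the threshold without real
    amplification, producing implausibly low Ct values; observed cells with
    ``Ct < floor`` become ``flagged_outlier``.  ``exclude`` may be an
    iterable of ``(detector, sample)`` pairs or a boolean DataFrame; those
    cells become ``excluded_by_user`` regardless of value.
    """
    if floor <= 0:
        raise InputError("floor must be positive")
    out = ct.copy()
    mask = out.observed_mask() & (out.ct < floor)
    out.ct[mask] = np.nan
    out.missing_reason[mask] = qio.REASON_FLAGGED_OUTLIER
    n = int(mask.to_numpy().sum())
    if n:
        log.info("flagged %d cells with Ct < %g as outliers", n, floor)
    if exclude is not None:
        if isinstance(exclude, pd.DataFrame):
            excl = exclude.reindex(index=out.ct.index, columns=out.ct.columns, fill_value=False)
            excl = excl.astype(bool)
        else:
            excl = pd.DataFrame(False, index=out.ct.index, columns=out.ct.columns)
            for det, smp in exclude:
                excl.loc[det, smp] = True
        out.ct[excl] = np.nan
        out.missing_reason[excl] = qio.REASON_EXCLUDED
    return out


# ---------------------------------------------------------------------------
# relative quantities
# ---------------------------------------------------------------------------

def compute_rq_spike(ct: CtMatrix, spike_id: str) -> RQMatrix:
    """RQ against an exogenous spike-in: ``rq_ij = 2^-(ct_ij - ct_spike,j)``.

    The spike must be observed in every sample; its row is removed from the
    candidate matrix (it is an external technical control, not a candidate
    normalizer).  Missing Ct propagates to missing RQ.
    """
    if spike_id not in ct.ct.index:
        raise ConfigError(f"spike detector {spike_id!r} not present in the Ct table")
    spike_ct = ct.ct.loc[spike_id]
    absent = list(spike_ct.index[spike_ct.isna()])
    if absent:
        raise DataError(
            f"spike {spike_id!r} missing in sample(s): {', '.join(map(str, absent))}"
        )
    rest = ct.ct.drop(index=spike_id)
    rq = np.exp2(-(rest.sub(spike_ct, axis=1)))
    return RQMatrix(rq, reference_mode=MODE_SPIKE, reference_id=spike_id)


def compute_rq_min_ct(ct: CtMatrix) -> RQMatrix:
    """RQ against the highest-expressed detector (minimum mean Ct).

    The reference is the detector with the lowest arithmetic-mean Ct among
    those observed in every sample (ties broken by lexicographically
    smaller id); its own row has rq = 1 everywhere and is retained.
    """
    complete = ct.observed_mask().all(axis=1)
    candidates = list(ct.ct.index[complete])
    if not candidates:
        raise DataError("no detector observed in all samples; cannot pick a min-Ct reference")
    means = ct.ct.loc[candidates].mean(axis=1)
    ref = min(candidates, key=lambda d: (means[d], str(d)))
    rq = np.exp2(-(ct.ct.sub(ct.ct.loc[ref], axis=1)))
    return RQMatrix(rq, reference_mode=MODE_MIN_CT, reference_id=ref)


# ---------------------------------------------------------------------------
# detection filter, imputation, pseudo-detectors
# ---------------------------------------------------------------------------

def detection_threshold(fraction: float, n: int) -> int:
    """Minimum present count for 'detected in at least `fraction` of n'."""
    # small epsilon guards ceil against float representation of e.g. 2/3
    return math.ceil(fraction * n - 1e-9)


def filter_detection(rq: RQMatrix, ann: SampleAnnotation, fraction: float = 2.0 / 3.0) -> RQMatrix:
    """Keep detectors detected in at least ``fraction`` of samples per group.

    A detector is retained iff in *every* group its present count is at
    least ``ceil(fraction * n_g)``; a candidate normalizer must be stably
    detected across all groups, so a single failing group disqualifies.
    """
    if not 0 < fraction <= 1:
        raise InputError("fraction must be in (0, 1]")
    groups = ann.groups_of(rq.sample_ids)
    present = rq.rq.notna()
    keep = pd.Series(True, index=rq.rq.index)
    for g, samples in groups.items():
        need = detection_threshold(fraction, len(samples))
        keep &= present[samples].sum(axis=1) >= need
    if not keep.any():
        raise DataError("no detector passes the detection filter")
    removed = list(rq.rq.index[~keep])
    if removed:
        log.info("detection filter removed %d detector(s): %s", len(removed), ", ".join(removed))
    return rq.replace(rq.rq.loc[keep], rq.pseudo_flags.loc[keep])


def impute_knn(rq: RQMatrix, k: int = 10) -> RQMatrix:
    """Impute residual missing RQs by k-nearest-neighbour on the log2 scale.

    For a missing cell the neighbours are the ``k`` detectors closest in
    nan-Euclidean distance over jointly observed samples; the imputed value
    is the inverse-distance-weighted mean of their log2 RQs in that sample,
    back-transformed.  Observed cells are unchanged.
    """
    from sklearn.impute import KNNImputer

    if k < 1:
        raise InputError("k must be >= 1")
    values = rq.rq.to_numpy(dtype=float)
    if not np.isnan(values).any():
        return rq.copy()
    m = values.shape[0]
    if m < 2:
        raise DataError("need at least 2 detectors to impute")
    logx = np.log2(values)
    # a detector with missing cells must share observed samples with someone
    present = np.isfinite(logx)
    overlap = present.astype(int) @ present.astype(int).T
    np.fill_diagonal(overlap, 0)
    rows_with_missing = np.where(~present.all(axis=1))[0]
    lonely = [rq.rq.index[i] for i in rows_with_missing if overlap[i].max() == 0]
    if lonely:
        raise DataError(
            "detector(s) with no jointly observed samples against any other: "
            + ", ".join(map(str, lonely))
        )
    imputer = KNNImputer(n_neighbors=min(k, m - 1), weights="distance")
    filled = imputer.fit_transform(logx)
    if filled.shape[0] != m or np.isnan(filled).any():
        raise DataError("k-NN imputation failed to fill all missing cells")
    out = pd.DataFrame(np.exp2(filled), index=rq.rq.index, columns=rq.rq.columns)
    out[rq.rq.notna()] = rq.rq  # observed cells bit-identical
    return rq.replace(out)


def add_pseudo_detectors(rq: RQMatrix) -> RQMatrix:
    """Append per-sample arithmetic mean, geometric mean and median rows.

    The three central-tendency pseudo-detectors compete with real miRNAs as
    candidate normalizers; they are flagged so they never enter real-detector
    column sums and are never selectable as references.
    """
    if rq.pseudo_flags.any():
        raise InputError("pseudo-detectors already present")
    if not rq.is_complete():
        raise InputError("pseudo-detectors require a complete (imputed) matrix")
    real = rq.rq
    extra = pd.DataFrame(
        {
            PSEUDO_MEAN: real.mean(axis=0),
            PSEUDO_GEOMEAN: np.exp2(np.log2(real).mean(axis=0)),
            PSEUDO_MEDIAN: real.median(axis=0),
        }
    ).T
    extra.columns = real.columns
    out = pd.concat([real, extra])
    flags = pd.Series(False, index=out.index)
    flags[list(PSEUDO_IDS)] = True
    return RQMatrix(out, rq.reference_mode, rq.reference_id, flags)
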