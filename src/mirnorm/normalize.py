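"""Normalization factors and normalized relative quantities.

The endogenous normalization factor (NF) of sample *j* is the geometric
mean of the selected reference detectors' RQs in that sample; alternatively
a global central tendency (arithmetic mean, geometric mean or median) of
all expressed detectors can serve as NF.  Normalized relative quantities
are ``NRQ_ij = RQ_ij / NF_j``.  When a spike-in was used to form the RQs,
the spike stage and this endogenous stage compose multiplicatively (the
two-level strategy): the spike corrects extraction/RT yield, the NF
corrects what an external control cannot see.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, InputError
from .preprocess import RQMatrix

METHOD_REFERENCES = "references"
GLOBAL_METHODS = {
    "arithmetic": "global_arithmetic_mean",
    "geometric": "global_geometric_mean",
    "median": "global_median",
}


@dataclass
class NormalizationResult:
    """Per-sample factors, the reference set used, and the NRQ matrix."""

    nf: pd.Series
    method: str
    reference_set: list[str] = field(default_factory=list)
    nrq: pd.DataFrame | None = None


def normalization_factor(rq: RQMatrix, refs: list[str]) -> pd.Series:
    """Geometric mean of the selected references' RQs, per sample."""
    if not refs:
        raise InputError("empty reference set")
    missing = [r for r in refs if r not in rq.rq.index]
    if missing:
        raise InputError(f"reference(s) not in matrix: {', '.join(missing)}")
    sub = rq.rq.loc[list(refs)]
    na = sub.isna()
    if na.to_numpy().any():
        det, smp = next(zip(*np.where(na.to_numpy())))
        raise DataError(
            f"reference {sub.index[det]!r} missing in sample {sub.columns[smp]!r}"
        )
    nf = sub.prod(axis=0) ** (1.0 / len(refs))
    nf.name = "nf"
    return nf


def global_nf(rq: RQMatrix, method: str = "geometric") -> pd.Series:
    """Central tendency of real-detector RQs per sample (pseudo rows excluded)."""
    if method not in GLOBAL_METHODS:
        raise InputError(f"method must be one of {sorted(GLOBAL_METHODS)}")
    real = rq.real
    if real.shape[0] == 0:
        raise InputError("no real detectors to summarize")
    if real.isna().to_numpy().any():
        raise InputError("global NF requires a complete matrix over real detectors")
    if method == "arithmetic":
        nf = real.mean(axis=0)
    elif method == "geometric":
        nf = np.exp2(np.log2(real).mean(axis=0))
    else:
        nf = real.median(axis=0)
    nf.name = "nf"
    return nf


def normalize_rq(
    rq: RQMatrix,
    nf: pd.Series,
    method: str = METHOD_REFERENCES,
    reference_set: list[str] | None = None,
) -> NormalizationResult:
    """Divide every sample column by its normalization factor."""
    if not nf.index.equals(rq.rq.columns):
        nf = nf.reindex(rq.rq.columns)
    if nf.isna().any() or len(nf) != rq.rq.shape[1]:
        raise InputError("need exactly one NF per sample")
    if (nf <= 0).any():
        raise InputError("normalization factors must be strictly positive")
    nrq = rq.rq.div(nf, axis=1)
    return NormalizationResult(
        nf=nf.copy(), method=method, reference_set=list(reference_set or []), nrq=nrq
    )


def normalize_by_references(rq: RQMatrix, refs: list[str]) -> NormalizationResult:
    """NF from the reference set, then NRQ; the references' per-sample
    geometric mean equals 1 after normalization (algebraic identity)."""
    nf = normalization_factor(rq, refs)
    return normalize_rq(rq, nf, METHOD_REFERENCES, refs)


def normalize_global(rq: RQMatrix, method: str = "geometric") -> NormalizationResult:
    """NF from a global central tendency, then NRQ."""
    nf = global_nf(rq, method)
    return normalize_rq(rq, nf, GLOBAL_METHODS[method], [])
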