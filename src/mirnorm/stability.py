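"""Stability scoring of candidate reference miRNAs.

Three complementary stability measures are computed on a complete, positive
RQ matrix and combined into a single summarized stability score (SSS):

* **geNorm M** — for every pair of detectors the pairwise variation
  ``V(j,k)`` is the sample SD over samples of ``log2(rq_j / rq_k)``; a
  detector's M is the average V against all others.  The least stable
  detector (highest M) is removed and the cycle repeated down to the final
  pair; the score reported per detector is its M in the round of its
  elimination (stepwise M), the canonical geNorm output.
* **Normfinder-style stability value (rho)** — a model-based decomposition
  of ``log2(rq)`` into detector, sample and group effects: intragroup
  variances are estimated per detector from two-way centered residuals with
  an ``I/(I-2)`` moment correction, intergroup differences are shrunk
  towards zero by their estimated reliability, and both are combined so
  that lower rho means a smaller systematic error for that candidate.
* **CV score** — each sample's column is converted to shares of the total
  RQ of that sample (a surrogate of total miRNA recovery), and the score is
  the coefficient of variation (SD/mean) of a detector's share across
  samples; a good normalizer tracks the total miRNA amount, giving a flat
  share profile.

All three are invariant to per-sample multiplicative scaling.  The SSS is
the Euclidean distance from the origin in score space,
``sqrt(M^2 + rho^2 + cv^2)``; candidates are ranked by ascending SSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, InputError, SelectionError
from .io import FamilyMap, SampleAnnotation
from .preprocess import RQMatrix

_SSS_COLUMNS = ["genorm_M", "normfinder_rho", "cv_score", "sss", "rank", "family", "pseudo"]


def _as_frame(rq) -> pd.DataFrame:
    frame = rq.rq if isinstance(rq, RQMatrix) else rq
    vals = frame.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise InputError("stability scores require a complete matrix; impute first")
    if (vals <= 0).any() or not np.isfinite(vals).all():
        raise InputError("rq values must be strictly positive and finite")
    return frame


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

@dataclass
class GeNormResult:
    """Output of the iterative geNorm procedure.

    ``stepwise_m`` holds each detector's M at its elimination round (the
    final pair shares the M of the last round); ``rounds`` holds the full
    per-round M tables for inspection.
    """

    stepwise_m: pd.Series
    elimination_order: list[str]
    final_pair: tuple[str, str]
    rounds: list[pd.Series] = field(default_factory=list)

    @property
    def ranking(self) -> list[str]:
        """Detectors from most to least stable (reverse elimination order)."""
        return list(reversed(self.elimination_order))


def _pairwise_v(logx: np.ndarray) -> np.ndarray:
    """V(j,k) = sample SD over samples of log2 ratios, for all pairs."""
    diff = logx[:, None, :] - logx[None, :, :]
    return diff.std(axis=2, ddof=1)


def genorm(rq) -> GeNormResult:
    """Run the iterative geNorm stability analysis.

    Requires >= 3 detectors and >= 2 samples.  Ties on the highest M are
    broken by removing the lexicographically larger id first, making the
    elimination order deterministic.
    """
    frame = _as_frame(rq)
    ids = [str(i) for i in frame.index]
    if len(ids) < 3:
        raise InputError("geNorm requires at least 3 detectors")
    if frame.shape[1] < 2:
        raise InputError("geNorm requires at least 2 samples")
    logx = np.log2(frame.to_numpy(dtype=float))

    remaining = list(ids)
    cur = logx
    stepwise: dict[str, float] = {}
    order: list[str] = []
    rounds: list[pd.Series] = []
    while len(remaining) > 2:
        v = _pairwise_v(cur)
        m = v.sum(axis=1) / (len(remaining) - 1)
        rounds.append(pd.Series(m, index=list(remaining), name=f"round_{len(rounds) + 1}"))
        worst = max(range(len(remaining)), key=lambda t: (m[t], remaining[t]))
        det = remaining[worst]
        stepwise[det] = float(m[worst])
        order.append(det)
        remaining.pop(worst)
        cur = np.delete(cur, worst, axis=0)
    v_last = float(_pairwise_v(cur)[0, 1])
    rounds.append(pd.Series([v_last, v_last], index=list(remaining), name=f"round_{len(rounds) + 1}"))
    for det in remaining:
        stepwise[det] = v_last
    pair = tuple(sorted(remaining))
    order.extend(sorted(remaining, reverse=True))
    return GeNormResult(
        stepwise_m=pd.Series({d: stepwise[d] for d in ids}, name="genorm_M"),
        elimination_order=order,
        final_pair=pair,  # type: ignore[arg-type]
        rounds=rounds,
    )


def genorm_pairwise_v(rq, ranking: list[str] | None = None) -> pd.Series:
    """Pairwise variation V(n, n+1) between successive normalization factors.

    ``NF_n`` is the per-sample geometric mean of the top-n detectors of the
    stability ranking; ``V(n, n+1)`` is the sample SD over samples of
    ``log2(NF_n / NF_{n+1})``, the standard aid for choosing how many
    references to use.  Defined for n = 2 .. m-1.
    """
    frame = _as_frame(rq)
    if ranking is None:
        ranking = genorm(frame).ranking
    if set(ranking) != set(map(str, frame.index)) or len(ranking) != frame.shape[0]:
        raise InputError("ranking must be a permutation of the matrix detectors")
    m = len(ranking)
    if m < 3:
        raise InputError("pairwise V requires at least 3 detectors")
    logx = np.log2(frame.loc[ranking].to_numpy(dtype=float))
    cums = np.cumsum(logx, axis=0)
    vals = {}
    for n in range(2, m):
        mean_n = cums[n - 1] / n
        mean_n1 = cums[n] / (n + 1)
        vals[n] = float(np.std(mean_n - mean_n1, ddof=1))
    out = pd.Series(vals, name="V")
    out.index.name = "n"
    return out


# ---------------------------------------------------------------------------
# Normfinder-style model-based stability
# ---------------------------------------------------------------------------

def normfinder(rq, ann: SampleAnnotation) -> pd.Series:
    """Model-based stability value (rho) per detector; lower is more stable.

    Fits the two-way model ``y_igj = detector + sample + noise`` within each
    group on ``y = log2(rq)``.  Per group the intragroup variance of each
    detector is estimated from the centered residuals with the ``I/(I-2)``
    moment correction (truncated at zero).  With >= 2 groups the intergroup
    difference of each detector is estimated, shrunk by its reliability
    ``gamma^2 / (gamma^2 + sigma^2/n)``, and combined with the uncertainty
    term into rho; with a single group rho is simply the intragroup SD.
    """
    frame = _as_frame(rq)
    ids = list(frame.index)
    n_det = len(ids)
    if n_det < 3:
        raise InputError("normfinder requires at least 3 detectors")
    groups = ann.groups_of(list(frame.columns))
    n_groups = len(groups)
    sizes = {g: len(s) for g, s in groups.items()}
    if any(n < 2 for n in sizes.values()):
        bad = [g for g, n in sizes.items() if n < 2]
        raise InputError(f"each group needs >= 2 samples; too small: {', '.join(bad)}")

    y = np.log2(frame.to_numpy(dtype=float))
    col_of = {s: j for j, s in enumerate(frame.columns)}

    sigma2 = np.empty((n_det, n_groups))
    ybar_ig = np.empty((n_det, n_groups))
    ns = np.empty(n_groups)
    for gi, (g, samples) in enumerate(groups.items()):
        cols = [col_of[s] for s in samples]
        yg = y[:, cols]
        ng = yg.shape[1]
        row_mean = yg.mean(axis=1)
        col_mean = yg.mean(axis=0)
        grand = yg.mean()
        resid = yg - row_mean[:, None] - col_mean[None, :] + grand
        u = (resid**2).sum(axis=1) / (ng - 1)
        sigma2[:, gi] = np.maximum(
            0.0, (n_det / (n_det - 2)) * (u - u.sum() / (n_det * (n_det - 1)))
        )
        ybar_ig[:, gi] = row_mean
        ns[gi] = ng

    if n_groups == 1:
        rho = np.sqrt(sigma2[:, 0])
    else:
        ybar_i = y.mean(axis=1)  # pooled over all samples
        dhat = (ybar_ig - ybar_ig.mean(axis=0)[None, :]) - (ybar_i - ybar_i.mean())[:, None]
        sig_over_n = sigma2 / ns[None, :]
        gamma2 = np.maximum(
            0.0, (dhat**2).sum(axis=1) / (n_groups - 1) - sig_over_n.mean(axis=1)
        )
        denom = gamma2[:, None] + sig_over_n
        with np.errstate(invalid="ignore", divide="ignore"):
            shrink = np.where(denom > 0, gamma2[:, None] / denom, 0.0)
            dtilde = dhat * shrink
            var_term = np.where(denom > 0, gamma2[:, None] * sig_over_n / denom, 0.0)
        rho = (np.abs(dtilde) + np.sqrt(var_term + sig_over_n)).mean(axis=1)
    return pd.Series(rho, index=ids, name="normfinder_rho")


# ---------------------------------------------------------------------------
# CV score
# ---------------------------------------------------------------------------

def cv_score(rq) -> pd.Series:
    """Coefficient of variation of each detector's share of the sample total.

    Column sums run over real (non-pseudo) detectors only; pseudo rows are
    scored against the same real-detector totals but never contribute to
    them.
    """
    if isinstance(rq, RQMatrix):
        frame = _as_frame(rq)
        totals = rq.real.sum(axis=0)
    else:
        frame = _as_frame(rq)
        totals = frame.sum(axis=0)
    if (totals <= 0).any():
        raise DataError("zero column sum; cannot form RQ shares")
    shares = frame.div(totals, axis=1)
    out = shares.std(axis=1, ddof=1) / shares.mean(axis=1)
    out.name = "cv_score"
    return out


# ---------------------------------------------------------------------------
# SSS and selection
# ---------------------------------------------------------------------------

@dataclass
class StabilityTable:
    """Per-detector stability scores, combined SSS and rank.

    The table is sorted by rank (ascending SSS, ties broken by detector id);
    ``rescaled`` records whether the three scores were min-max rescaled to
    [0, 1] before combination (the stored score columns are the ones that
    entered the SSS).
    """

    table: pd.DataFrame
    platform: str = ""
    rescaled: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in _SSS_COLUMNS if c not in self.table.columns]
        if missing:
            raise InputError(f"stability table missing column(s): {', '.join(missing)}")
        scores = self.table[["genorm_M", "normfinder_rho", "cv_score"]].to_numpy(dtype=float)
        expect = np.sqrt((scores**2).sum(axis=1))
        if np.abs(expect - self.table["sss"].to_numpy(dtype=float)).max() > 1e-12:
            raise InputError("sss column inconsistent with the three scores")
        ranks = sorted(self.table["rank"])
        if ranks != list(range(1, len(self.table) + 1)):
            raise InputError("ranks must be a permutation of 1..m")

    @property
    def detector_ids(self) -> list[str]:
        return list(self.table.index)

    def ranked(self) -> pd.DataFrame:
        return self.table.sort_values("rank")


def _minmax(s: pd.Series) -> pd.Series:
    lo, hi = float(s.min()), float(s.max())
    if hi > lo:
        return (s - lo) / (hi - lo)
    return pd.Series(0.0, index=s.index)


def sss(
    genorm_m: pd.Series,
    rho: pd.Series,
    cv: pd.Series,
    *,
    rescale: bool = False,
    families: FamilyMap | None = None,
    pseudo_flags: pd.Series | None = None,
    platform: str = "",
) -> StabilityTable:
    """Combine the three scores into the summarized stability score.

    ``sss_i = sqrt(M_i^2 + rho_i^2 + cv_i^2)`` on the raw score scales by
    default; with ``rescale=True`` each score is first min-max rescaled to
    [0, 1] to address scale mismatch between methods.  Rows are ranked by
    ascending SSS with detector-id tie-break, so the output is independent
    of the input detector order.
    """
    sets = [set(genorm_m.index), set(rho.index), set(cv.index)]
    if sets[0] != sets[1] or sets[0] != sets[2]:
        raise InputError("the three score vectors must cover the same detectors")
    ids = sorted(map(str, genorm_m.index))
    m = genorm_m.reindex(ids).astype(float)
    r = rho.reindex(ids).astype(float)
    c = cv.reindex(ids).astype(float)
    if rescale:
        m, r, c = _minmax(m), _minmax(r), _minmax(c)
    combined = np.sqrt(m**2 + r**2 + c**2)
    order = sorted(ids, key=lambda d: (combined[d], d))
    rank = pd.Series({d: i + 1 for i, d in enumerate(order)})
    if pseudo_flags is None:
        pseudo_flags = pd.Series(False, index=ids)
    fam = families or FamilyMap.singletons(ids)
    table = pd.DataFrame(
        {
            "genorm_M": m,
            "normfinder_rho": r,
            "cv_score": c,
            "sss": combined,
            "rank": rank,
            "family": [fam.family(d) for d in ids],
            "pseudo": pseudo_flags.reindex(ids).fillna(False).astype(bool),
        },
        index=ids,
    ).sort_values("rank")
    table.index.name = "detector"
    return StabilityTable(table, platform=platform, rescaled=rescale)


def score_stability(
    rq: RQMatrix,
    ann: SampleAnnotation,
    families: FamilyMap | None = None,
    *,
    rescale: bool = False,
    stepwise_m: bool = True,
    platform: str = "",
) -> StabilityTable:
    """Convenience wrapper: run geNorm, normfinder and CV score, combine.

    ``stepwise_m=False`` uses the single-pass full-set M instead of the
    stepwise (elimination-round) M as the geNorm score entering the SSS.
    """
    gres = genorm(rq)
    if stepwise_m:
        m = gres.stepwise_m
    else:
        m = gres.rounds[0].reindex(gres.stepwise_m.index)
        m.name = "genorm_M"
    return sss(
        m,
        normfinder(rq, ann),
        cv_score(rq),
        rescale=rescale,
        families=families,
        pseudo_flags=rq.pseudo_flags,
        platform=platform,
    )


def select_references(tab: StabilityTable, fam: FamilyMap, k: int) -> list[str]:
    """Pick the top-k references walking ranks ascending.

    Pseudo-detectors are skipped, and only one member per miRNA family is
    admitted (family members share sequence similarity and likely
    functional overlap).
    """
    if k < 1:
        raise InputError("k must be >= 1")
    chosen: list[str] = []
    used_families: set[str] = set()
    for det, row in tab.ranked().iterrows():
        if bool(row["pseudo"]):
            continue
        family = fam.family(str(det))
        if family in used_families:
            continue
        chosen.append(str(det))
        used_families.add(family)
        if len(chosen) == k:
            return chosen
    raise SelectionError(
        f"requested {k} references but only {len(chosen)} admissible candidate(s) available"
    )


def combine_platforms(tabs: list[StabilityTable]) -> pd.DataFrame:
    """Combine stability tables from >= 2 platforms over shared detectors.

    Each platform's SSS is min-max rescaled to [0, 1] over the detectors
    present in *all* tables, and the combined score is the arithmetic mean
    of the rescaled scores, ranked ascending.
    """
    if len(tabs) < 2:
        raise InputError("need at least 2 platform tables")
    labels = []
    for i, t in enumerate(tabs):
        lab = t.platform or f"platform{i + 1}"
        if lab in labels:
            lab = f"{lab}_{i + 1}"
        labels.append(lab)
    shared = set(tabs[0].detector_ids)
    for t in tabs[1:]:
        shared &= set(t.detector_ids)
    if not shared:
        raise DataError("no detector shared by all platforms")
    ids = sorted(shared)
    out = pd.DataFrame(index=ids)
    out.index.name = "detector"
    rescaled = []
    for lab, t in zip(labels, tabs):
        s = t.table.loc[ids, "sss"].astype(float)
        out[f"sss_{lab}"] = s
        rs = _minmax(s)
        out[f"rescaled_{lab}"] = rs
        rescaled.append(rs)
    out["combined_score"] = sum(rescaled) / len(rescaled)
    order = sorted(ids, key=lambda d: (out.loc[d, "combined_score"], d))
    out["rank"] = pd.Series({d: i + 1 for i, d in enumerate(order)})
    return out.sort_values("rank")
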