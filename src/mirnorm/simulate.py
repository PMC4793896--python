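"""Synthetic circulating-miRNA qPCR experiments with known ground truth.

The generator emulates the dominant noise sources of serum miRNA panels on
the Ct (log2) scale, where multiplicative biology becomes additive:

* a per-detector baseline Ct drawn uniformly over a realistic abundance
  window (default 20-32 cycles);
* class-specific biological noise: *stable* detectors vary little (log2 SD
  0.05), *variable* detectors a lot (log2 SD 0.5), *de* detectors carry an
  additional group shift (default 1 log2 unit, i.e. a 2-fold difference);
* a per-sample scaling factor ``s_j`` (log2 SD 1.0 by default)
  representing inter-individual differences in total miRNA concentration
  and RNA input, applied to every endogenous detector of the sample;
* a spike-in detector carrying only small technical noise (log2 SD 0.05):
  the spike is added at a fixed concentration, so by default it does *not*
  carry ``s_j`` and spike normalization cannot remove that component —
  exactly the limitation of external controls that motivates endogenous
  normalization.  Set ``spike_shares_scaling=True`` to model a spike that
  is co-extracted and absorbs ``s_j`` too.
* detection censoring: simulated Ct values above ``ct_threshold`` are
  reported as undetermined.

Everything is reproducible from one integer seed; each matrix section
draws from its own deterministically spawned substream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io as qio
from .errors import ConfigError, InputError
from .io import CtMatrix, SampleAnnotation
from .stability import StabilityTable

SPIKE_ID = "spike-in"

CLASS_STABLE = "stable"
CLASS_VARIABLE = "variable"
CLASS_DE = "de"


@dataclass
class SimConfig:
    """Ground-truth parameters of one synthetic experiment."""

    m_stable: int = 5
    m_variable: int = 15
    m_de: int = 10
    n_per_group: int = 8
    groups: int = 2
    baseline_ct_range: tuple[float, float] = (20.0, 32.0)
    stable_sd: float = 0.05
    variable_sd: float = 0.5
    de_effect: float = 1.0
    sample_scaling_sd: float = 1.0
    spike_noise_sd: float = 0.05
    ct_threshold: float = 35.0
    seed: int = 0
    spike_id: str = SPIKE_ID
    spike_baseline_ct: float = 20.0
    spike_shares_scaling: bool = False

    def validate(self) -> None:
        for name in ("stable_sd", "variable_sd", "sample_scaling_sd", "spike_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("m_stable", "m_variable", "m_de"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.m_stable + self.m_variable + self.m_de < 3:
            raise ConfigError("need at least 3 detectors in total")
        if self.groups < 1 or self.n_per_group < 1:
            raise ConfigError("groups and n_per_group must be >= 1")
        lo, hi = self.baseline_ct_range
        if not 0 < lo <= hi:
            raise ConfigError("baseline_ct_range must satisfy 0 < low <= high")
        if self.ct_threshold <= 0:
            raise ConfigError("ct_threshold must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_ct_range"] = list(self.baseline_ct_range)
        return d


@dataclass
class SimTruth:
    """Per-detector class labels, baselines and per-sample true factors."""

    class_labels: pd.Series        # detector -> stable|variable|de
    baseline_ct: pd.Series         # detector -> true baseline Ct
    sample_scaling_log2: pd.Series  # sample -> s_j (log2)
    seed: int = 0

    @property
    def sample_factors(self) -> pd.Series:
        """Per-sample multiplicative factor on the linear RQ scale."""
        return np.exp2(self.sample_scaling_log2).rename("factor")

    def detectors_of(self, label: str) -> list[str]:
        return list(self.class_labels.index[self.class_labels == label])


def simulate_ct(cfg: SimConfig) -> tuple[CtMatrix, SampleAnnotation, SimTruth]:
    """Generate one synthetic Ct experiment (spike row included)."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_base, rng_noise, rng_sample, rng_spike = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    labels = (
        [CLASS_STABLE] * cfg.m_stable
        + [CLASS_VARIABLE] * cfg.m_variable
        + [CLASS_DE] * cfg.m_de
    )
    width = len(str(len(labels)))
    counters = {CLASS_STABLE: 0, CLASS_VARIABLE: 0, CLASS_DE: 0}
    detectors = []
    for lab in labels:
        counters[lab] += 1
        detectors.append(f"{lab}-{counters[lab]:0{width}d}")
    m = len(detectors)
    n = cfg.groups * cfg.n_per_group
    samples = [
        f"g{g + 1}_s{s + 1}" for g in range(cfg.groups) for s in range(cfg.n_per_group)
    ]
    group_of = np.repeat(np.arange(cfg.groups), cfg.n_per_group)

    lo, hi = cfg.baseline_ct_range
    baseline = rng_base.uniform(lo, hi, size=m)
    sds = np.where(np.array(labels) == CLASS_STABLE, cfg.stable_sd, cfg.variable_sd)
    deviation = rng_noise.normal(0.0, 1.0, size=(m, n)) * sds[:, None]
    # group effect: de detectors shifted up in the second group (if any)
    shift = np.zeros((m, n))
    if cfg.groups >= 2 and cfg.m_de:
        de_rows = np.array([lab == CLASS_DE for lab in labels])
        shift[np.ix_(de_rows, group_of == 1)] = cfg.de_effect
    s_j = rng_sample.normal(0.0, cfg.sample_scaling_sd, size=n)

    # higher abundance -> lower Ct: subtract log2-abundance deviations
    ct = baseline[:, None] - deviation - shift - s_j[None, :]
    spike_eps = rng_spike.normal(0.0, cfg.spike_noise_sd, size=n)
    spike_ct = cfg.spike_baseline_ct + spike_eps
    if cfg.spike_shares_scaling:
        spike_ct = spike_ct - s_j

    full = np.vstack([ct, spike_ct[None, :]])
    ids = detectors + [cfg.spike_id]
    reason = np.full(full.shape, qio.REASON_OBSERVED, dtype=object)
    censored = full > cfg.ct_threshold
    reason[censored] = qio.REASON_UNDETERMINED
    full = np.where(censored, np.nan, full)

    ctm = CtMatrix(
        pd.DataFrame(full, index=ids, columns=samples),
        pd.DataFrame(reason, index=ids, columns=samples),
        platform="simulated",
    )
    ann = SampleAnnotation(
        pd.DataFrame(
            {"group": [f"group{g + 1}" for g in group_of]},
            index=pd.Index(samples, name="sample_id"),
        )
    )
    truth = SimTruth(
        class_labels=pd.Series(labels, index=detectors, name="class"),
        baseline_ct=pd.Series(baseline, index=detectors, name="baseline_ct"),
        sample_scaling_log2=pd.Series(s_j, index=samples, name="s_log2"),
        seed=cfg.seed,
    )
    return ctm, ann, truth


def truth_recovery(tab: StabilityTable, truth: SimTruth, top_k: int) -> dict:
    """How well the SSS ranking recovers the designed-stable detectors.

    Returns the number of designed-stable detectors among the ``top_k``
    ranked rows and the mean rank of the designed-stable detectors.
    """
    real = [d for d in tab.detector_ids if not bool(tab.table.loc[d, "pseudo"])]
    if top_k > len(real):
        raise InputError("top_k exceeds the number of real detectors")
    unknown = [d for d in real if d not in truth.class_labels.index]
    if unknown:
        raise InputError(
            "detector(s) not covered by the simulation truth: " + ", ".join(unknown)
        )
    ranked = tab.ranked()
    top = list(ranked.index[:top_k])
    stable = set(truth.detectors_of(CLASS_STABLE)) & set(real)
    n_hit = len(stable & set(top))
    mean_rank = float(ranked.loc[sorted(stable), "rank"].mean()) if stable else float("nan")
    return {"n_stable_in_top_k": n_hit, "mean_rank_stable": mean_rank, "top_k": top_k}
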