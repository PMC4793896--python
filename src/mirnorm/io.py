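"""Reading and writing Ct tables, sample annotations and miRNA family maps.

The canonical orientation is *wide*: detectors (assayed miRNAs) as rows,
samples as columns.  A transposed file is rejected rather than guessed,
because silent transposition would corrupt every downstream statistic.

Missing Ct values carry an explicit per-cell reason code so that censoring,
outlier flagging and user exclusions remain distinguishable through the
pipeline:

``observed``          a finite, positive Ct value is present
``undetermined``      the instrument reported no amplification
``above_threshold``   censored because Ct exceeded the platform threshold
``flagged_outlier``   removed by the extreme-low-Ct quality rule
``excluded_by_user``  removed by an explicit user mask

Result tables are written as TSV with a header row; the Ct writer emits
shortest round-trip decimal representations so write/read cycles are
bit-stable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

REASON_OBSERVED = "observed"
REASON_UNDETERMINED = "undetermined"
REASON_ABOVE_THRESHOLD = "above_threshold"
REASON_FLAGGED_OUTLIER = "flagged_outlier"
REASON_EXCLUDED = "excluded_by_user"

MISSING_REASONS = (
    REASON_UNDETERMINED,
    REASON_ABOVE_THRESHOLD,
    REASON_FLAGGED_OUTLIER,
    REASON_EXCLUDED,
)
ALL_REASONS = (REASON_OBSERVED,) + MISSING_REASONS

#: tokens treated as "undetermined" when reading raw instrument exports;
#: matching is case-insensitive after trimming whitespace.
DEFAULT_UNDETERMINED_TOKENS = ("undetermined", "na", "")


def _delimiter_for(path: str | os.PathLike, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    ext = os.path.splitext(str(path))[1].lower()
    return "," if ext == ".csv" else "\t"


def _check_unique(labels, what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for lab in labels:
        if lab in seen and lab not in dups:
            dups.append(lab)
        seen.add(lab)
    if dups:
        raise FormatError(f"duplicate {what} id(s): {', '.join(map(str, dups))}")


@dataclass
class CtMatrix:
    """Raw threshold-cycle values with per-cell missingness reasons.

    Parameters
    ----------
    ct
        Detectors x samples matrix of Ct values (PCR cycles); ``NaN`` where
        the cell is not observed.
    missing_reason
        Matrix of reason codes with the same index/columns as ``ct``.
    platform
        Free-text platform label (e.g. ``"TaqMan"``).
    """

    ct: pd.DataFrame
    missing_reason: pd.DataFrame
    platform: str = ""

    def __post_init__(self) -> None:
        _check_unique(self.ct.index, "detector")
        _check_unique(self.ct.columns, "sample")
        if not (
            self.ct.index.equals(self.missing_reason.index)
            and self.ct.columns.equals(self.missing_reason.columns)
        ):
            raise FormatError("ct and missing_reason must share index and columns")
        bad = ~self.missing_reason.isin(ALL_REASONS)
        if bad.to_numpy().any():
            raise FormatError("unknown missing-reason code in CtMatrix")
        observed = self.missing_reason.to_numpy() == REASON_OBSERVED
        vals = self.ct.to_numpy(dtype=float)
        present = np.isfinite(vals)
        if not (observed == present).all():
            raise FormatError("observed cells must carry a finite Ct and vice versa")
        if (vals[present] <= 0).any():
            raise FormatError("observed Ct values must be strictly positive")

    @property
    def detector_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def n_detectors(self) -> int:
        return self.ct.shape[0]

    @property
    def n_samples(self) -> int:
        return self.ct.shape[1]

    def observed_mask(self) -> pd.DataFrame:
        return self.missing_reason == REASON_OBSERVED

    def missing_counts(self) -> pd.Series:
        """Number of cells per reason code (observed included)."""
        return (
            pd.Series(self.missing_reason.to_numpy().ravel())
            .value_counts()
            .reindex(ALL_REASONS, fill_value=0)
        )

    def copy(self) -> "CtMatrix":
        return CtMatrix(self.ct.copy(), self.missing_reason.copy(), self.platform)


@dataclass
class SampleAnnotation:
    """Sample-level metadata: biological group and optional batch/platform.

    ``group_levels`` preserves the order in which groups first appear in the
    input file; all group-wise computations iterate in that order.
    """

    table: pd.DataFrame  # index: sample_id; columns: group [, batch, platform]
    group_levels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        if "group" not in self.table.columns:
            raise FormatError("sample annotation requires a 'group' column")
        grp = self.table["group"]
        if grp.isna().any() or (grp.astype(str).str.strip() == "").any():
            missing = list(self.table.index[grp.isna() | (grp.astype(str).str.strip() == "")])
            raise FormatError(f"missing group value for sample(s): {', '.join(map(str, missing))}")
        if not self.group_levels:
            self.group_levels = list(pd.unique(grp))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def group(self) -> pd.Series:
        return self.table["group"]

    def require_samples(self, sample_ids) -> None:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ConsistencyError(
                f"sample(s) absent from annotation: {', '.join(map(str, missing))}"
            )

    def groups_of(self, sample_ids) -> dict[str, list[str]]:
        """Samples per group (group-level order), restricted to ``sample_ids``."""
        self.require_samples(sample_ids)
        grp = self.table.loc[list(sample_ids), "group"]
        out: dict[str, list[str]] = {}
        for g in self.group_levels:
            members = [s for s in sample_ids if grp[s] == g]
            if members:
                out[g] = members
        return out


@dataclass
class FamilyMap:
    """Total map detector -> miRNA family.

    Detectors absent from the input annotation are assigned singleton
    families named after themselves, so the map is always total once
    :meth:`completed` has been applied.
    """

    mapping: dict[str, str] = field(default_factory=dict)

    def family(self, detector: str) -> str:
        return self.mapping.get(detector, detector)

    def completed(self, detectors) -> "FamilyMap":
        full = {d: self.mapping.get(d, d) for d in detectors}
        return FamilyMap(full)

    @classmethod
    def singletons(cls, detectors) -> "FamilyMap":
        return cls({d: d for d in detectors})


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_ct_table(
    path: str | os.PathLike,
    undetermined_tokens=DEFAULT_UNDETERMINED_TOKENS,
    delimiter: str | None = None,
    platform: str = "",
) -> CtMatrix:
    """Read a wide-format Ct table (detectors as rows, samples as columns).

    Cells must be numerals, a configured undetermined token (matched
    case-insensitively after trimming), or one of the reserved reason codes
    written by :func:`write_ct_table` (which makes write/read round trips
    lossless).
    """
    sep = _delimiter_for(path, delimiter)
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str, keep_default_na=False)
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise FormatError(f"{path}: need at least one detector row and one sample column")
    samples = [str(c).strip() for c in raw.iloc[0, 1:]]
    detectors = [str(d).strip() for d in raw.iloc[1:, 0]]
    _check_unique(detectors, "detector")
    _check_unique(samples, "sample")

    tokens = {t.strip().lower() for t in undetermined_tokens}
    ct = np.full((len(detectors), len(samples)), np.nan)
    reason = np.full(ct.shape, REASON_OBSERVED, dtype=object)
    for i, det in enumerate(detectors):
        for j, smp in enumerate(samples):
            cell = str(raw.iat[i + 1, j + 1]).strip()
            low = cell.lower()
            if low in tokens:
                reason[i, j] = REASON_UNDETERMINED
                continue
            if low in MISSING_REASONS:
                reason[i, j] = low
                continue
            try:
                val = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at detector {det!r}, sample {smp!r}"
                ) from None
            if not np.isfinite(val) or val <= 0:
                raise FormatError(
                    f"{path}: Ct must be finite and positive, got {cell!r} "
                    f"at detector {det!r}, sample {smp!r}"
                )
            ct[i, j] = val
    return CtMatrix(
        pd.DataFrame(ct, index=detectors, columns=samples),
        pd.DataFrame(reason, index=detectors, columns=samples),
        platform=platform,
    )


def write_ct_table(ctm: CtMatrix, path: str | os.PathLike, delimiter: str | None = None) -> None:
    """Write a CtMatrix; non-observed cells are written as their reason code."""
    sep = _delimiter_for(path, delimiter)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("detector" + sep + sep.join(map(str, ctm.sample_ids)) + "\n")
        vals = ctm.ct.to_numpy()
        reasons = ctm.missing_reason.to_numpy()
        for i, det in enumerate(ctm.detector_ids):
            cells = [
                repr(float(vals[i, j])) if reasons[i, j] == REASON_OBSERVED else reasons[i, j]
                for j in range(ctm.n_samples)
            ]
            fh.write(str(det) + sep + sep.join(cells) + "\n")


def read_sample_annotation(path: str | os.PathLike, delimiter: str | None = None) -> SampleAnnotation:
    """Read a sample annotation with columns sample_id, group [, batch, platform]."""
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if "sample_id" not in cols or "group" not in cols:
        raise FormatError(f"{path}: sample annotation requires columns sample_id and group")
    keep = [c for c in ("group", "batch", "platform") if c in cols]
    table = df.set_index(df["sample_id"].str.strip())[keep]
    table.index.name = "sample_id"
    for c in keep:
        table[c] = table[c].astype(str).str.strip()
    if (table["group"] == "").any():
        bad = list(table.index[table["group"] == ""])
        raise FormatError(f"{path}: missing group for sample(s): {', '.join(bad)}")
    return SampleAnnotation(table)


def read_family_annotation(path: str | os.PathLike, detectors, delimiter: str | None = None) -> FamilyMap:
    """Read a two-column detector->family file and complete it to a total map."""
    sep = _delimiter_for(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return FamilyMap.singletons(detectors)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: family annotation requires two columns")
    mapping: dict[str, str] = {}
    det_col, fam_col = df.columns[0], df.columns[1]
    for _, row in df.iterrows():
        det = str(row[det_col]).strip()
        fam = str(row[fam_col]).strip()
        if det in mapping and mapping[det] != fam:
            raise FormatError(
                f"{path}: detector {det!r} mapped to conflicting families "
                f"{mapping[det]!r} and {fam!r}"
            )
        mapping[det] = fam
    return FamilyMap(mapping).completed(detectors)


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a result table as TSV with a header row."""
    df.to_csv(path, sep="\t")
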