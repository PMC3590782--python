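"""Read and write the tabular formats shared by every pipeline stage.

The atomic input is a PSM (peptide-spectrum match) table: one row per
identified MS/MS spectrum carrying its replicate coordinates and the four
iTRAQ 4-plex reporter-ion intensities (channels 114-117).  The dialect is
deliberately minimal - header-keyed TSV, UTF-8, ``.`` decimal separator,
no quoting - which is the lowest common denominator of search-engine
exports.

An empty intensity cell means *not measured* and is parsed as missing
(NaN); this is distinct from an explicit ``0``, because a zero reporter
ion still counts toward spectral counts while an absent one may indicate
a spectrum where the reporter region was not recorded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: iTRAQ 4-plex reporter channels, in reporter m/z order.
CHANNELS: tuple[int, ...] = (114, 115, 116, 117)

#: Intensity column name for a channel.
INTENSITY_COLUMNS: dict[int, str] = {c: f"i{c}" for c in CHANNELS}

#: Exact PSM table header, in canonical order.
PSM_COLUMNS: tuple[str, ...] = (
    "protein_id",
    "peptide",
    "workflow_rep",
    "technical_rep",
    "fraction",
    "confidence",
    "i114",
    "i115",
    "i116",
    "i117",
)

_INT_COLUMNS = ("workflow_rep", "technical_rep", "fraction")
_CONFIDENCE_TIERS = ("medium", "high")


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match with its replicate coordinates.

    ``workflow_rep`` indexes an independent repetition of the whole
    sample-preparation-through-MS workflow; ``technical_rep`` indexes one
    cumulative LC-MS/MS analysis of all SCX fractions within it.
    Intensities are reporter-ion peak intensities in arbitrary units;
    ``None`` means the reporter was not measured.
    """

    protein_id: str
    peptide: str
    workflow_rep: int
    technical_rep: int
    fraction: int
    confidence: str
    i114: float | None
    i115: float | None
    i116: float | None
    i117: float | None

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if self.workflow_rep < 1 or self.technical_rep < 1 or self.fraction < 1:
            raise ValueError("replicate and fraction indices must be >= 1")
        if self.confidence not in _CONFIDENCE_TIERS:
            raise ValueError(
                f"confidence must be one of {_CONFIDENCE_TIERS}, got {self.confidence!r}"
            )
        for ch in CHANNELS:
            v = self.intensity(ch)
            if v is not None and (v < 0 or math.isnan(v)):
                raise ValueError(f"intensity i{ch} must be >= 0, got {v!r}")

    def intensity(self, channel: int) -> float | None:
        return getattr(self, f"i{channel}")


@dataclass
class ProteinList:
    """A named set of protein accessions (e.g. a plasma reference database)."""

    name: str
    accessions: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.accessions)


def validate_psm_frame(psms: pd.DataFrame, *, source: str = "<frame>") -> None:
    """Check a PSM table against the schema invariants.

    Raises ``ValueError`` naming the first offending row (1-based data row,
    i.e. file line minus header) and column.
    """
    missing = [c for c in PSM_COLUMNS if c not in psms.columns]
    if missing:
        raise ValueError(f"{source}: missing required column(s) {missing}")
    for col in _INT_COLUMNS:
        vals = pd.to_numeric(psms[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals.fillna(0)))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{source}: row {row + 1}, column {col!r}: "
                f"non-integer value {psms[col].iloc[row]!r}"
            )
        if (vals < 1).any():
            row = int(np.flatnonzero((vals < 1).to_numpy())[0])
            raise ValueError(f"{source}: row {row + 1}, column {col!r}: index < 1")
    empty_id = psms["protein_id"].astype(str).str.len() == 0
    if empty_id.any():
        row = int(np.flatnonzero(empty_id.to_numpy())[0])
        raise ValueError(f"{source}: row {row + 1}: empty protein_id")
    bad_conf = ~psms["confidence"].isin(_CONFIDENCE_TIERS)
    if bad_conf.any():
        row = int(np.flatnonzero(bad_conf.to_numpy())[0])
        raise ValueError(
            f"{source}: row {row + 1}, column 'confidence': "
            f"{psms['confidence'].iloc[row]!r} not in {_CONFIDENCE_TIERS}"
        )
    for ch in CHANNELS:
        col = INTENSITY_COLUMNS[ch]
        vals = pd.to_numeric(psms[col], errors="coerce")
        if psms[col].dtype == object:
            not_blank = psms[col].notna() & psms[col].astype(str).str.strip().ne("")
        else:
            not_blank = psms[col].notna()
        unparsable = not_blank & vals.isna()
        if unparsable.any():
            row = int(np.flatnonzero(unparsable.to_numpy())[0])
            raise ValueError(
                f"{source}: row {row + 1}, column {col!r}: "
                f"unparsable intensity {psms[col].iloc[row]!r}"
            )
        neg = vals < 0
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0])
            raise ValueError(
                f"{source}: row {row + 1}, column {col!r}: negative intensity "
                f"{vals.iloc[row]!r}"
            )


def read_psm_table(path) -> pd.DataFrame:
    """Read a PSM TSV into a typed DataFrame.

    Column order in the file is free (the header is authoritative).  Empty
    intensity cells become NaN.  Any malformed row fails the whole read
    with a message naming the row and column.
    """
    raw = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        keep_default_na=False,
        na_values=[],
        encoding="utf-8",
    )
    raw = raw.replace({"": None})
    for col in ("protein_id", "peptide", "confidence"):
        if col in raw.columns:
            raw[col] = raw[col].fillna("")
    validate_psm_frame(raw, source=str(path))
    out = pd.DataFrame(
        {
            "protein_id": raw["protein_id"].astype(str),
            "peptide": raw["peptide"].astype(str),
            "workflow_rep": raw["workflow_rep"].astype(int),
            "technical_rep": raw["technical_rep"].astype(int),
            "fraction": raw["fraction"].astype(int),
            "confidence": raw["confidence"].astype(str),
        }
    )
    for ch in CHANNELS:
        col = INTENSITY_COLUMNS[ch]
        out[col] = pd.to_numeric(raw[col], errors="raise").astype(float)
    logger.info("read %d PSMs from %s", len(out), path)
    return out


def write_psm_table(psms: pd.DataFrame, path) -> None:
    """Write a PSM table as TSV; floats at full round-trip precision."""
    validate_psm_frame(psms, source="write_psm_table")
    psms.loc[:, list(PSM_COLUMNS)].to_csv(
        path, sep="\t", index=False, na_rep="", encoding="utf-8"
    )
    logger.info("wrote %d PSMs to %s", len(psms), path)


def frame_to_records(psms: pd.DataFrame) -> list[PsmRecord]:
    """Materialise a PSM DataFrame as a list of validated records."""
    records = []
    for row in psms.itertuples(index=False):
        records.append(
            PsmRecord(
                protein_id=row.protein_id,
                peptide=row.peptide,
                workflow_rep=int(row.workflow_rep),
                technical_rep=int(row.technical_rep),
                fraction=int(row.fraction),
                confidence=row.confidence,
                i114=None if pd.isna(row.i114) else float(row.i114),
                i115=None if pd.isna(row.i115) else float(row.i115),
                i116=None if pd.isna(row.i116) else float(row.i116),
                i117=None if pd.isna(row.i117) else float(row.i117),
            )
        )
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Inverse of :func:`frame_to_records`."""
    return pd.DataFrame([r.__dict__ for r in records], columns=PSM_COLUMNS).astype(
        {c: float for c in INTENSITY_COLUMNS.values()}
    )


def read_protein_list(path, name: str | None = None) -> ProteinList:
    """Read a plain-text accession list (one per line, ``#`` comments).

    Duplicates are collapsed; an empty file yields an empty list with a
    warning rather than an error.
    """
    accessions: set[str] = set()
    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if not entry:
                continue
            n_lines += 1
            accessions.add(entry)
    if n_lines == 0:
        logger.warning("protein list %s is empty", path)
    elif len(accessions) < n_lines:
        logger.info(
            "protein list %s: %d lines collapsed to %d unique accessions",
            path,
            n_lines,
            len(accessions),
        )
    else:
        logger.info("protein list %s: %d accessions", path, len(accessions))
    return ProteinList(name=name or str(path), accessions=accessions)


def write_protein_list(plist: ProteinList, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for acc in sorted(plist.accessions):
            fh.write(acc + "\n")
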