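"""Spectral-count filtering and median peptide-to-protein ratio roll-up.

Identification and quantitation are governed by separate spectral-count
(SC) filters: a protein is *identified* in a workflow replicate when it
has at least ``min_sc`` PSMs pooled over that replicate's technical
replicates and fractions, and it is *quantifiable* in a technical
replicate when it has at least ``min_sc`` PSMs within that single run.
Two SC in one technical replicate imply two in its workflow replicate,
so quantitation eligibility is strictly stronger than identification.

Quantification itself: for every PSM whose reference-channel intensity
is present and positive, each other channel's peptide ratio is the plain
intensity quotient; the protein ratio in a technical replicate is the
median of its peptide ratios for that channel.  A PSM with a zero or
missing reference intensity contributes no ratios but still counts
toward spectral counts - identification and quantitation are decoupled
by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import CHANNELS, INTENSITY_COLUMNS, PsmRecord

logger = logging.getLogger(__name__)

#: Canonical columns of the tidy (long) protein-quantification table.
QUANT_COLUMNS = (
    "protein_id",
    "workflow_rep",
    "technical_rep",
    "spectral_count",
    "channel",
    "ratio",
    "n_peptide_ratios",
)


@dataclass
class ProteinQuant:
    """One protein's quantification in one technical replicate."""

    protein_id: str
    workflow_rep: int
    technical_rep: int
    spectral_count: int
    #: channel -> protein ratio (median peptide ratio vs. the reference)
    ratio_by_channel: dict[int, float] = field(default_factory=dict)
    #: channel -> number of peptide ratios the median was taken over
    n_peptide_ratios: dict[int, int] = field(default_factory=dict)


def _check_min_sc(min_sc: int) -> None:
    if min_sc < 1:
        raise ValueError("min_sc must be >= 1")


def spectral_counts(psms: pd.DataFrame) -> pd.DataFrame:
    """PSM count per (protein, workflow replicate, technical replicate).

    Confidence tiers are pooled: medium- and high-confidence PSMs both
    count.
    """
    return (
        psms.groupby(["protein_id", "workflow_rep", "technical_rep"], sort=True)
        .size()
        .rename("spectral_count")
        .reset_index()
    )


def filter_identification(psms: pd.DataFrame, min_sc: int = 2) -> dict[int, set[str]]:
    """Proteins identified per workflow replicate.

    A protein is retained for a workflow replicate iff its pooled PSM
    count there (all technical replicates, all fractions, both confidence
    tiers) is at least ``min_sc``.
    """
    _check_min_sc(min_sc)
    if psms.empty:
        raise ValueError("PSM table is empty")
    counts = psms.groupby(["workflow_rep", "protein_id"]).size()
    kept = counts[counts >= min_sc]
    out: dict[int, set[str]] = {
        int(wr): set() for wr in psms["workflow_rep"].unique()
    }
    for (wr, pid), _n in kept.items():
        out[int(wr)].add(pid)
    return out


def filter_quantitation(
    psms: pd.DataFrame, min_sc: int = 2
) -> set[tuple[str, int, int]]:
    """(protein, workflow_rep, technical_rep) triples eligible for quantitation.

    Eligibility requires at least ``min_sc`` PSMs within the single
    technical replicate.
    """
    _check_min_sc(min_sc)
    if psms.empty:
        raise ValueError("PSM table is empty")
    sc = spectral_counts(psms)
    sc = sc[sc["spectral_count"] >= min_sc]
    return {
        (row.protein_id, int(row.workflow_rep), int(row.technical_rep))
        for row in sc.itertuples(index=False)
    }


def peptide_ratios(record: PsmRecord, reference_channel: int = 114) -> dict[int, float]:
    """Reporter-ion ratios of one PSM relative to the reference channel.

    Channels with zero or missing intensity yield no ratio; a zero or
    missing reference excludes the whole PSM from quantitation (logged,
    not fatal).
    """
    if reference_channel not in CHANNELS:
        raise ValueError(f"reference channel must be one of {CHANNELS}")
    ref = record.intensity(reference_channel)
    if ref is None or ref <= 0:
        logger.debug(
            "PSM %s/%s excluded from ratios: reference i%d is %r",
            record.protein_id,
            record.peptide,
            reference_channel,
            ref,
        )
        return {}
    out = {}
    for ch in CHANNELS:
        if ch == reference_channel:
            continue
        v = record.intensity(ch)
        if v is not None and v > 0:
            out[ch] = v / ref
    return out


def psm_ratio_table(psms: pd.DataFrame, reference_channel: int = 114) -> pd.DataFrame:
    """Long table of per-PSM peptide ratios (vectorised ``peptide_ratios``).

    Columns: protein_id, workflow_rep, technical_rep, channel, ratio.
    """
    if reference_channel not in CHANNELS:
        raise ValueError(f"reference channel must be one of {CHANNELS}")
    ref = psms[INTENSITY_COLUMNS[reference_channel]].to_numpy(dtype=float)
    ref_ok = np.isfinite(ref) & (ref > 0)
    n_excluded = int((~ref_ok).sum())
    if n_excluded:
        logger.info(
            "%d PSMs excluded from quantitation (reference i%d zero/absent)",
            n_excluded,
            reference_channel,
        )
    pieces = []
    for ch in CHANNELS:
        if ch == reference_channel:
            continue
        val = psms[INTENSITY_COLUMNS[ch]].to_numpy(dtype=float)
        ok = ref_ok & np.isfinite(val) & (val > 0)
        piece = psms.loc[ok, ["protein_id", "workflow_rep", "technical_rep"]].copy()
        piece["channel"] = ch
        piece["ratio"] = val[ok] / ref[ok]
        pieces.append(piece)
    if not pieces:
        return pd.DataFrame(
            columns=["protein_id", "workflow_rep", "technical_rep", "channel", "ratio"]
        )
    return pd.concat(pieces, ignore_index=True)


def protein_ratio(ratios) -> float:
    """Protein ratio = median of the peptide ratios for one channel.

    Even counts use the arithmetic mean of the two central values.
    """
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one peptide ratio is required")
    if np.any(arr <= 0):
        raise ValueError("peptide ratios must be > 0")
    return float(np.median(arr))


def quantify_proteins(
    psms: pd.DataFrame,
    reference_channel: int = 114,
    min_sc: int = 2,
) -> pd.DataFrame:
    """Protein-level ratios per technical replicate, after the SC filter.

    Returns a tidy table (one row per protein x technical replicate x
    channel) with the spectral count, the median peptide ratio and the
    number of peptide ratios behind it.  Channels with no eligible
    peptide ratio are simply absent.
    """
    sc = spectral_counts(psms)
    sc = sc[sc["spectral_count"] >= min_sc]  # the quantitation SC filter

    ratios = psm_ratio_table(psms, reference_channel=reference_channel)
    if ratios.empty:
        return pd.DataFrame(columns=list(QUANT_COLUMNS))
    key = ["protein_id", "workflow_rep", "technical_rep"]
    agg = (
        ratios.groupby(key + ["channel"], sort=True)["ratio"]
        .agg(ratio="median", n_peptide_ratios="size")
        .reset_index()
    )
    agg = agg.merge(sc, on=key, how="inner")
    agg = agg.loc[:, list(QUANT_COLUMNS)].reset_index(drop=True)
    agg["n_peptide_ratios"] = agg["n_peptide_ratios"].astype(int)
    logger.info(
        "quantified %d protein x replicate x channel ratios "
        "(reference %d, min SC %d)",
        len(agg),
        reference_channel,
        min_sc,
    )
    return agg


def quant_to_records(quants: pd.DataFrame) -> list[ProteinQuant]:
    """Group a tidy quant table into per-replicate :class:`ProteinQuant`."""
    out = []
    for (pid, wr, tr), grp in quants.groupby(
        ["protein_id", "workflow_rep", "technical_rep"], sort=True
    ):
        out.append(
            ProteinQuant(
                protein_id=pid,
                workflow_rep=int(wr),
                technical_rep=int(tr),
                spectral_count=int(grp["spectral_count"].iloc[0]),
                ratio_by_channel={
                    int(c): float(r) for c, r in zip(grp["channel"], grp["ratio"])
                },
                n_peptide_ratios={
                    int(c): int(n)
                    for c, n in zip(grp["channel"], grp["n_peptide_ratios"])
                },
            )
        )
    return out


def quant_wide(quants: pd.DataFrame, reference_channel: int = 114) -> pd.DataFrame:
    """Pivot the tidy quant table to one row per protein x technical replicate.

    Ratio columns are named ``ratio_<channel>_<reference>`` to make the
    reference explicit in exported files.
    """
    if quants.empty:
        return pd.DataFrame(
            columns=["protein_id", "workflow_rep", "technical_rep", "spectral_count"]
        )
    key = ["protein_id", "workflow_rep", "technical_rep", "spectral_count"]
    wide = quants.pivot_table(
        index=key, columns="channel", values=["ratio", "n_peptide_ratios"]
    )
    wide.columns = [
        f"{'ratio' if kind == 'ratio' else 'n_peptides'}_{int(ch)}_{reference_channel}"
        for kind, ch in wide.columns
    ]
    return wide.reset_index()
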