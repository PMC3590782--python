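"""Synthetic PSM tables with the statistical structure of a 4-plex design.

The generator emulates a multiplexed shotgun experiment in which four
samples are labeled with iTRAQ 4-plex reagents (reporter channels
114-117), pooled, fractionated into SCX fractions and analysed by
repeated LC-MS/MS runs, with the whole workflow itself repeated from
fresh aliquots.  Every variance component the downstream statistics
estimate is an explicit dial:

* ``s_b`` - between-workflow-replicate ("biological") variation, the CV
  of a protein's channel ratio across workflow replicates;
* ``s_t`` - between-technical-replicate variation, the CV of the ratio
  across LC-MS/MS runs within one workflow replicate;
* ``s_psm`` - spectrum-level reporter measurement noise, which makes
  low-spectral-count proteins noisier than high-count ones (the
  CV-versus-spectral-count trend seen in real reporter-ion data).

All noise is multiplicative log-normal.  A requested fractional CV ``s``
on the *ratio* scale is realised by drawing each channel's factor with
log-scale variance ``ln(1 + s^2)/2``: the log-ratio of two such factors
then has variance ``ln(1 + s^2)``, i.e. the linear-scale CV of the ratio
is exactly ``s``.

Spectral counts are negative-binomial with per-protein means drawn
log-uniformly, so protein abundance spans orders of magnitude as it does
in plasma.  Per-replicate dropout is a Bernoulli proxy for the partial
overlap of identification lists across workflow replicates; it can
optionally be coupled to abundance so that low-count proteins drop out
more often.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import CHANNELS, PSM_COLUMNS

logger = logging.getLogger(__name__)

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQSTVWY"))

#: Non-reference channels, in m/z order (ratios are taken against 114).
_RATIO_CHANNELS = (115, 116, 117)


@dataclass
class SimDesign:
    """Parameters of one simulated 4-plex experiment.

    Defaults reproduce the study design the analysis assumes: 4 channels
    mixed 1:1:1:1, 3 workflow x 3 technical replicates, 13 SCX fractions,
    s_b = 0.16, s_t = 0.10, 80% per-replicate detection.
    """

    n_proteins: int = 2000
    #: true abundance ratio of channels 115, 116, 117 relative to 114
    channel_fold_changes: tuple[float, float, float] = (1.0, 1.0, 1.0)
    s_b: float = 0.16
    s_t: float = 0.10
    #: spectrum-level reporter noise (ratio-scale CV per PSM)
    s_psm: float = 0.10
    n_workflow_reps: int = 3
    n_technical_reps: int = 3
    n_fractions: int = 13
    #: log10 interval for the per-protein expected spectral count per run
    sc_mean_log10_range: tuple[float, float] = (0.3, 2.3)
    #: negative-binomial dispersion (shape) for spectral counts
    nb_dispersion: float = 4.0
    detection_prob: float = 0.8
    #: slope coupling detection probability to log10 abundance (0 = none)
    detection_abundance_slope: float = 0.0
    #: log10 interval for per-protein reference-channel base intensity
    base_intensity_range: tuple[float, float] = (1e4, 1e7)
    #: log-scale SD of the per-PSM overall intensity (cancels in ratios)
    psm_scale_sigma: float = 1.0
    #: probability a PSM is tiered "high" rather than "medium" confidence
    high_confidence_prob: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first violated invariant."""
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if len(self.channel_fold_changes) != len(_RATIO_CHANNELS):
            raise ValueError(
                "channel_fold_changes needs one entry per non-reference channel "
                f"({len(_RATIO_CHANNELS)})"
            )
        if any(f <= 0 for f in self.channel_fold_changes):
            raise ValueError("channel fold changes must be > 0")
        for name in ("s_b", "s_t", "s_psm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} (a CV) must be >= 0")
        for name in ("n_workflow_reps", "n_technical_reps", "n_fractions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in [0, 1]")
        if not 0.0 <= self.high_confidence_prob <= 1.0:
            raise ValueError("high_confidence_prob must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        lo, hi = self.sc_mean_log10_range
        if lo > hi:
            raise ValueError("sc_mean_log10_range must be a non-empty interval")
        blo, bhi = self.base_intensity_range
        if blo <= 0 or blo > bhi:
            raise ValueError("base_intensity_range must be a positive interval")
        if self.psm_scale_sigma < 0:
            raise ValueError("psm_scale_sigma must be >= 0")


def _sigma_per_channel(cv: float) -> float:
    # log-scale SD per channel such that a two-channel ratio has linear CV `cv`
    return math.sqrt(math.log1p(cv * cv) / 2.0)


def _peptide_sequences(rng: np.random.Generator, n: int) -> list[str]:
    # tryptic-looking decoys: 7-19 interior residues ending in K or R
    lengths = rng.integers(7, 20, size=n)
    seqs = []
    for ln in lengths:
        body = "".join(_AMINO_ACIDS[rng.integers(0, len(_AMINO_ACIDS), size=ln)])
        seqs.append(body + ("K" if rng.random() < 0.5 else "R"))
    return seqs


def true_ratio(design: SimDesign, channel: int) -> float:
    """Configured abundance ratio of ``channel`` relative to channel 114."""
    if channel == CHANNELS[0]:
        return 1.0
    return design.channel_fold_changes[_RATIO_CHANNELS.index(channel)]


def generate_psm_table(design: SimDesign) -> pd.DataFrame:
    """Draw one PSM table from the design.

    Deterministic given ``design.seed``; per-protein random sub-streams
    are spawned from the global seed so each protein's draws are
    independent.  Returns a DataFrame in the canonical PSM schema.
    """
    design.validate()
    root = np.random.SeedSequence(design.seed)
    children = root.spawn(design.n_proteins)

    n_ch = len(CHANNELS)
    folds = np.array([true_ratio(design, c) for c in CHANNELS])
    sig_b = _sigma_per_channel(design.s_b)
    sig_t = _sigma_per_channel(design.s_t)
    sig_p = _sigma_per_channel(design.s_psm)
    lo_sc, hi_sc = design.sc_mean_log10_range
    lo_b, hi_b = np.log10(design.base_intensity_range)
    mid_sc = 0.5 * (lo_sc + hi_sc)
    r = design.nb_dispersion

    cols: dict[str, list] = {c: [] for c in PSM_COLUMNS}

    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"SYN{i + 1:05d}"
        mu = 10.0 ** rng.uniform(lo_sc, hi_sc)
        base = 10.0 ** rng.uniform(lo_b, hi_b)

        p_det = design.detection_prob + design.detection_abundance_slope * (
            math.log10(mu) - mid_sc
        )
        p_det = min(1.0, max(0.0, p_det))
        detected = rng.random(design.n_workflow_reps) < p_det

        n_pep = max(1, int(math.ceil(2.0 * math.sqrt(mu))))
        peptides = _peptide_sequences(rng, n_pep)
        pep_fraction = rng.integers(1, design.n_fractions + 1, size=n_pep)

        # biological noise: one factor per workflow replicate x channel
        bio = (
            np.exp(rng.normal(0.0, sig_b, size=(design.n_workflow_reps, n_ch)))
            if sig_b > 0
            else np.ones((design.n_workflow_reps, n_ch))
        )

        for wr in range(design.n_workflow_reps):
            if not detected[wr]:
                continue
            for tr in range(design.n_technical_reps):
                k = int(rng.negative_binomial(r, r / (r + mu)))
                if k == 0:
                    continue
                tech = (
                    np.exp(rng.normal(0.0, sig_t, size=n_ch))
                    if sig_t > 0
                    else np.ones(n_ch)
                )
                pep_idx = rng.integers(0, n_pep, size=k)
                scale = base * (
                    np.exp(rng.normal(0.0, design.psm_scale_sigma, size=k))
                    if design.psm_scale_sigma > 0
                    else np.ones(k)
                )
                psm_noise = (
                    np.exp(rng.normal(0.0, sig_p, size=(k, n_ch)))
                    if sig_p > 0
                    else np.ones((k, n_ch))
                )
                inten = scale[:, None] * folds[None, :] * bio[wr][None, :]
                inten = inten * tech[None, :] * psm_noise
                conf = np.where(
                    rng.random(k) < design.high_confidence_prob, "high", "medium"
                )

                cols["protein_id"].extend([pid] * k)
                cols["peptide"].extend(peptides[j] for j in pep_idx)
                cols["workflow_rep"].extend([wr + 1] * k)
                cols["technical_rep"].extend([tr + 1] * k)
                cols["fraction"].extend(int(pep_fraction[j]) for j in pep_idx)
                cols["confidence"].extend(conf.tolist())
                for ci, ch in enumerate(CHANNELS):
                    cols[f"i{ch}"].extend(inten[:, ci].tolist())

    out = pd.DataFrame(cols, columns=list(PSM_COLUMNS))
    logger.info(
        "generated %d PSMs for %d proteins (seed=%d)",
        len(out),
        design.n_proteins,
        design.seed,
    )
    return out


def design_from_mapping(params: dict) -> SimDesign:
    """Build a :class:`SimDesign` from a flat key-value mapping.

    Keys mirror the dataclass fields; unknown keys are rejected so typos
    in config files fail loudly.
    """
    known = set(SimDesign.__dataclass_fields__)
    unknown = set(params) - known
    if unknown:
        raise ValueError(f"unknown SimDesign parameter(s): {sorted(unknown)}")
    params = dict(params)
    for key in ("channel_fold_changes", "sc_mean_log10_range", "base_intensity_range"):
        if key in params and isinstance(params[key], (list, tuple)):
            params[key] = tuple(float(v) for v in params[key])
    design = SimDesign(**params)
    design.validate()
    return design
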