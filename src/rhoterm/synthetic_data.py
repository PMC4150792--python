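"""Seeded generators for synthetic inputs with the structure each stage assumes.

Four experiment types are emulated, none of which exist as deposited data:

* release/ATPase time courses -- true curves from the kinetic model, turned
  back into gel band intensities with multiplicative lognormal noise
  (densitometry is positive and ratio-scale);
* two-condition expression tables -- a fixed-size gene universe with a
  planted affected set, of which only a fraction responds to PBS mutants
  (the PBS-insensitive subset emulates terminators that do not need the
  primary binding site);
* transcript-sense sequences with one planted rut window (C-rich,
  unstructured) inside a hairpin-cassette background;
* qRT-PCR Ct quadruplets consistent with planted fold changes.

Every generator is a pure function of its config: the same seed reproduces
byte-identical output.  The generators emulate the *statistical* structure
of the assays, not instrument physics (no dye bias, probe effects, gel
smile, or PCR efficiency below 2); see docs/methods.md for what passing
benchmarks on these data does and does not establish.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetic_model import ChainSpec, RateParameters, TimeCourse, simulate_release_analytic
from .kinetics_fitting import ReleaseMeasurement

__all__ = [
    "SynthConfig",
    "RELEASE_ASSAY_SLOW",
    "RELEASE_ASSAY_FAST",
    "RELEASE_ASSAY_CHAIN",
    "RELEASE_ASSAY_TIMES",
    "gen_release_timecourse",
    "gen_expression_tables",
    "gen_rut_sequences",
    "gen_ct_table",
    "write_fasta",
    "write_bed",
]

# distinct sub-stream ids so the four generators draw independent randomness
# from one seed
_STREAM_RELEASE, _STREAM_EXPR, _STREAM_SEQ, _STREAM_CT = 1, 2, 3, 4

# ---------------------------------------------------------------------------
# Reference release-assay conditions
# ---------------------------------------------------------------------------
# One fixed, physically-motivated in-vitro condition set used by the worked
# examples and benchmarks: ~50 nM Rho at ~1e6 /M/s (k_on 0.05/s), stable rut
# engagement (k_off 0.01/s), translocation at 60 nt/s over 200 nt (seconds,
# invisible at gel sampling resolution), dislodging at 2/s, NusG accelerating
# isomerization 100-fold.  Isomerization is resolved into 5 sub-stages: the
# large concerted ring-closure transition behaves as a low-variance multi-step
# process, which is what gives slow-recruitment terminators their lag phase.
# The slow condition (k_iso 0.05/s) emulates a weak-recruitment (trac-like)
# terminator, the fast one (k_iso 5/s) a classical (tR1-like) terminator.
# Sampling starts at 10 s (manual-sampling dead time) and stays within the
# informative part of the curve.
RELEASE_ASSAY_SLOW = RateParameters(k_on=0.05, k_off=0.01, k_iso=0.05,
                                    k_step=60.0, k_dislodge=2.0,
                                    nusg_factor=100.0)
RELEASE_ASSAY_FAST = RELEASE_ASSAY_SLOW.with_(k_iso=5.0)
RELEASE_ASSAY_CHAIN = ChainSpec(n_steps=200, n_iso_stages=5)
RELEASE_ASSAY_TIMES = np.linspace(10.0, 180.0, 20)

#: Base probabilities of the planted rut window (C-rich, G-poor).
RUT_BASE_PROBS = {"C": 0.45, "A": 0.25, "U": 0.20, "G": 0.10}


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of all synthetic generators.

    Defaults encode the emulated study: a 4294-gene expression chip with
    ~550 genes affected by SBS mutants of which ~80% are insensitive to PBS
    mutants (~110 PBS-affected), gel densitometry noise of 0.02 on the
    fraction scale, a null expression scatter of 0.3 log2 units, planted
    effects of ~4 +/- 0.6 log2 units, 300-nt regions with one 60-nt rut
    window, and qRT-PCR Ct noise of 0.2 cycles.
    """

    seed: int = 0
    noise_sd: float = 0.02
    n_genes: int = 4294
    n_affected: int = 550
    frac_pbs_insensitive: float = 0.8
    effect_log2_mean: float = 4.0
    effect_log2_sd: float = 0.6
    sigma_null: float = 0.3
    frac_up: float = 0.7
    seq_count: int = 100
    seq_length: int = 300
    rut_length: int = 60
    sigma_ct: float = 0.2
    total_intensity: float = 100.0
    release_amplitude: float = 0.8

    def __post_init__(self) -> None:
        if self.n_affected > self.n_genes:
            raise ValueError("n_affected cannot exceed n_genes")
        for name in ("frac_pbs_insensitive", "frac_up"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.rut_length > self.seq_length:
            raise ValueError("rut_length cannot exceed seq_length")
        for name in ("noise_sd", "sigma_null", "sigma_ct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


# ---------------------------------------------------------------------------
# Release time courses
# ---------------------------------------------------------------------------

def gen_release_timecourse(params: RateParameters, chain: ChainSpec,
                           times: Sequence[float], cfg: SynthConfig,
                           nusg: bool = False,
                           ) -> tuple[list[ReleaseMeasurement], TimeCourse]:
    """Noisy gel measurements of a model release curve, plus the true curve.

    The released fraction is ``release_amplitude * F(t)`` with F from the
    master equation -- release assays saturate well below 1 because a
    fraction of complexes never releases, so the observable plateaus around
    the amplitude (default 0.8).  The observed fraction is the true one
    times exp(sigma * Z) (multiplicative lognormal, sigma =
    ``cfg.noise_sd``), clipped to [0, 1], and band intensities are
    back-computed from a fixed total of ``cfg.total_intensity`` units:
    S = total * f / 2 (half the supernatant) and S+P = total - S.  The
    returned truth curve carries the amplitude scaling.
    """
    model = simulate_release_analytic(params, chain, times, nusg=nusg)
    truth = TimeCourse(model.times, cfg.release_amplitude * model.values,
                       kind="release")
    # fold the experimental condition into the noise stream so distinct
    # conditions get independent (but still seed-deterministic) noise
    condition = zlib.crc32(repr((params, chain, tuple(np.asarray(times, float)),
                                 nusg)).encode())
    rng = np.random.default_rng([int(cfg.seed), _STREAM_RELEASE, condition])
    noisy = np.clip(truth.values * np.exp(cfg.noise_sd *
                                          rng.standard_normal(truth.values.size)),
                    0.0, 1.0)
    half = cfg.total_intensity / 2.0
    measurements = [
        ReleaseMeasurement(time=float(t), s_half=float(half * f),
                           s_plus_p=float(cfg.total_intensity - half * f))
        for t, f in zip(truth.times, noisy)
    ]
    return measurements, truth


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def _truncated_effects(rng: np.random.Generator, n: int, mean: float,
                       sd: float, lower: float) -> np.ndarray:
    """|log2 FC| of planted effects: Normal(mean, sd) resampled above lower."""
    out = rng.normal(mean, sd, size=n)
    bad = out < lower
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(np.count_nonzero(bad)))
        bad = out < lower
    return out


def gen_expression_tables(cfg: SynthConfig, fold_threshold: float = 5.0,
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Planted two-condition expression tables (PBS, SBS) plus truth labels.

    All ``cfg.n_affected`` planted genes respond to the SBS mutant; only the
    complement of the PBS-insensitive fraction also responds to the PBS
    mutant.  Planted |log2 FC| values are Normal(effect_log2_mean,
    effect_log2_sd) truncated at the fold cutoff so every planted gene is a
    true positive by construction; signs are up with probability
    ``cfg.frac_up``.  Unaffected genes scatter as Normal(0, sigma_null) in
    log2.  Returns (pbs_table, sbs_table, truth) where truth has boolean
    columns affected_sbs / affected_pbs / sbs_only.
    """
    rng = cfg._rng(_STREAM_EXPR)
    gene_ids = np.array([f"gene_{i:05d}" for i in range(cfg.n_genes)])
    affected = rng.choice(cfg.n_genes, size=cfg.n_affected, replace=False)
    n_pbs = int(round((1.0 - cfg.frac_pbs_insensitive) * cfg.n_affected))
    pbs_affected = rng.choice(affected, size=n_pbs, replace=False)

    cutoff = math.log2(fold_threshold)
    magnitudes = _truncated_effects(rng, cfg.n_affected, cfg.effect_log2_mean,
                                    cfg.effect_log2_sd, cutoff)
    signs = np.where(rng.random(cfg.n_affected) < cfg.frac_up, 1.0, -1.0)
    effect_sbs = np.zeros(cfg.n_genes)
    effect_sbs[affected] = signs * magnitudes
    effect_pbs = np.zeros(cfg.n_genes)
    mask_pbs = np.isin(affected, pbs_affected)
    effect_pbs[affected[mask_pbs]] = (signs * magnitudes)[mask_pbs]

    wt = rng.lognormal(mean=8.0, sigma=1.0, size=cfg.n_genes)

    def table(effect: np.ndarray) -> pd.DataFrame:
        lfc = effect + rng.normal(0.0, cfg.sigma_null, size=cfg.n_genes)
        return pd.DataFrame({"gene_id": gene_ids, "category": "coding",
                             "wt": wt, "mut": wt * np.exp2(lfc)})

    pbs_table = table(effect_pbs)
    sbs_table = table(effect_sbs)
    aff_sbs = np.zeros(cfg.n_genes, dtype=bool)
    aff_sbs[affected] = True
    aff_pbs = np.zeros(cfg.n_genes, dtype=bool)
    aff_pbs[pbs_affected] = True
    truth = pd.DataFrame({"gene_id": gene_ids, "affected_sbs": aff_sbs,
                          "affected_pbs": aff_pbs,
                          "sbs_only": aff_sbs & ~aff_pbs,
                          "true_log2fc_sbs": effect_sbs,
                          "true_log2fc_pbs": effect_pbs})
    return pbs_table, sbs_table, truth


# ---------------------------------------------------------------------------
# rut-bearing sequences
# ---------------------------------------------------------------------------

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _stem_loop_cassette(rng: np.random.Generator) -> str:
    """A G/C stem-loop: 8-12 bp perfect stem around a 4-6 nt random loop."""
    stem_len = int(rng.integers(8, 13))
    loop_len = int(rng.integers(4, 7))
    stem = "".join(rng.choice(["G", "C"], size=stem_len))
    loop = "".join(rng.choice(["A", "C", "G", "U"], size=loop_len))
    return stem + loop + "".join(_COMP[b] for b in reversed(stem))


def gen_rut_sequences(cfg: SynthConfig,
                      ) -> tuple[list[tuple[str, str]], list[tuple[str, int, int]]]:
    """Transcript-sense sequences with one planted rut window each.

    The background is a concatenation of strong G/C stem-loop cassettes
    (deeply negative folding energy, C/G ratio ~ 1); the planted window is
    drawn from :data:`RUT_BASE_PROBS` (expected C/G count ratio 4.5, little
    structure) and overwrites the background at a random position.  Returns
    ``(records, truth)`` where records are (name, sequence) and truth holds
    (name, start, end) of each planted window in 0-based half-open
    coordinates.
    """
    rng = cfg._rng(_STREAM_SEQ)
    bases = list(RUT_BASE_PROBS)
    probs = np.array([RUT_BASE_PROBS[b] for b in bases])
    records, truth = [], []
    for i in range(cfg.seq_count):
        chunks: list[str] = []
        total = 0
        while total < cfg.seq_length:
            c = _stem_loop_cassette(rng)
            chunks.append(c)
            total += len(c)
        background = "".join(chunks)[:cfg.seq_length]
        start = int(rng.integers(0, cfg.seq_length - cfg.rut_length + 1))
        rut = "".join(rng.choice(bases, size=cfg.rut_length, p=probs))
        seq = background[:start] + rut + background[start + cfg.rut_length:]
        name = f"region_{i:03d}"
        records.append((name, seq))
        truth.append((name, start, start + cfg.rut_length))
    return records, truth


def write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    """Write (name, sequence) records as two-line FASTA (deterministic bytes)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord
    seqs = [SeqRecord(Seq(s), id=n, description="") for n, s in records]
    with open(path, "w") as fh:
        seqio_write(seqs, fh, "fasta-2line")


def write_bed(intervals: Sequence[tuple[str, int, int]], path) -> None:
    """Write (name, start, end) truth intervals as BED3."""
    with open(path, "w") as fh:
        for name, start, end in intervals:
            fh.write(f"{name}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

def gen_ct_table(cfg: SynthConfig, true_folds: Mapping[str, float],
                 ct_target_wt: float = 24.0,
                 ct_control: float = 15.0) -> pd.DataFrame:
    """Ct quadruplets consistent with planted fold changes.

    A gene with fold f amplifies log2(f) cycles earlier in the mutant:
    ct_target_mut = ct_target_wt - log2(f) + Normal(0, sigma_ct).  Control
    Cts are constant, so the 2^-ddCt estimator recovers f without bias on
    the log scale.
    """
    rng = cfg._rng(_STREAM_CT)
    rows = []
    for gene, fold in true_folds.items():
        if fold <= 0:
            raise ValueError(f"true fold for {gene!r} must be > 0")
        ct_mut = (ct_target_wt - math.log2(fold)
                  + cfg.sigma_ct * rng.standard_normal())
        rows.append({"gene": gene, "ct_target_wt": ct_target_wt,
                     "ct_target_mut": ct_mut, "ct_control_wt": ct_control,
                     "ct_control_mut": ct_control, "true_fold": fold})
    return pd.DataFrame(rows)
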