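"""Synthetic data with the statistical structure the atlas analysis assumes.

Three generators cover the three downstream arms:

* :func:`simulate_counts` — negative-binomial counts under the mixed-effect
  generative model (fixed sex / age / region effects, Gaussian per-individual
  random effect, common over-dispersion theta) on a balanced
  2-sex x 2-age x individuals-per-cell design observed across R regions.
* :func:`simulate_linked_signals` — paired peak / expression intensity
  matrices with planted Pearson correlations for link-recovery checks.
* :func:`simulate_annotations` — a toy reference transcriptome and an
  "assembled" counterpart with controlled exon- and intron-level exact-match
  fractions, for assembly evaluation and lncRNA screening.

All generators are deterministic under a fixed seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, InvalidConfigError, TranscriptModel


@dataclass
class SimCountConfig:
    """Generative parameters for the NB mixed-effect count simulator.

    Effect sizes are on the natural-log scale of the NB mean (the model's
    link scale).  ``dispersion`` is the NB size parameter theta with
    variance mu + mu^2/theta.
    """

    n_genes: int = 500
    n_regions: int = 4
    n_individuals_per_cell: int = 2  # study design: 2 per sex x age cell
    n_replicates: int = 1
    baseline_log_mean: float = math.log(100.0)
    sex_effect_genes: float = 0.0
    sex_effect_size: float = 0.0
    age_effect_genes: float = 0.0
    age_effect_size: float = 0.0
    region_effect_sd: float = 0.3
    indiv_re_sd: float = 0.3
    dispersion: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_regions", "n_individuals_per_cell",
                     "n_replicates"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be a positive integer")
        for name in ("sex_effect_genes", "age_effect_genes"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        if self.dispersion <= 0:
            raise InvalidConfigError("dispersion theta must be > 0")
        if self.region_effect_sd < 0 or self.indiv_re_sd < 0:
            raise InvalidConfigError("effect SDs must be >= 0")
        for name in ("baseline_log_mean", "sex_effect_size", "age_effect_size",
                     "region_effect_sd", "indiv_re_sd", "dispersion"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidConfigError(f"{name} must be finite")


@dataclass
class SimTruth:
    """Ground-truth bookkeeping for a simulated count matrix."""

    sex_alt: np.ndarray          # bool, per gene
    age_alt: np.ndarray          # bool, per gene
    sex_effect: np.ndarray       # natural-log contrast, per gene
    age_effect: np.ndarray
    region_effects: np.ndarray   # genes x regions (reference region = 0)
    random_effects: pd.DataFrame = field(default=None)  # genes x individuals


def _design_table(config: SimCountConfig) -> pd.DataFrame:
    """Balanced design: every individual observed in all regions/replicates."""
    rows = []
    indiv = 0
    for sex in (0, 1):
        for age in (0, 1):
            for _ in range(config.n_individuals_per_cell):
                indiv += 1
                for region in range(1, config.n_regions + 1):
                    for rep in range(1, config.n_replicates + 1):
                        rows.append(
                            {
                                "sample_id": f"I{indiv:02d}_R{region:02d}_s{rep}",
                                "individual": f"I{indiv:02d}",
                                "sex": sex,
                                "age": age,
                                "region": f"R{region:02d}",
                                "replicate": rep,
                            }
                        )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_counts(config: SimCountConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw NB counts from the mixed-effect generative model.

    log mu = baseline + sex*alpha_g + age*beta_g + gamma_{g,region}
             + delta_{g,individual};  counts ~ NB(mu, theta).

    The first round(fraction * G) genes of a seeded permutation carry the
    sex (resp. age) contrast; the random effect delta is drawn once per
    gene per individual and shared across that individual's samples.
    """
    rng = np.random.default_rng(config.seed)
    samples = _design_table(config)
    G = config.n_genes
    genes = [f"g{i:05d}" for i in range(G)]
    individuals = samples["individual"].unique()

    n_sex = round(config.sex_effect_genes * G)
    n_age = round(config.age_effect_genes * G)
    sex_alt = np.zeros(G, dtype=bool)
    sex_alt[rng.permutation(G)[:n_sex]] = True
    age_alt = np.zeros(G, dtype=bool)
    age_alt[rng.permutation(G)[:n_age]] = True
    sex_eff = np.where(sex_alt, config.sex_effect_size, 0.0)
    age_eff = np.where(age_alt, config.age_effect_size, 0.0)

    # region effects: reference region 1 pinned at zero
    gamma = rng.normal(0.0, config.region_effect_sd, size=(G, config.n_regions))
    gamma[:, 0] = 0.0
    delta = rng.normal(0.0, config.indiv_re_sd, size=(G, len(individuals)))

    region_idx = samples["region"].str.slice(1).astype(int).to_numpy() - 1
    indiv_idx = pd.Categorical(samples["individual"],
                               categories=individuals).codes
    sex = samples["sex"].to_numpy()
    age = samples["age"].to_numpy()

    log_mu = (
        config.baseline_log_mean
        + sex_eff[:, None] * sex[None, :]
        + age_eff[:, None] * age[None, :]
        + gamma[:, region_idx]
        + delta[:, indiv_idx]
    )
    if not np.all(np.isfinite(log_mu)):
        raise InvalidConfigError("non-finite mean parameters")
    mu = np.exp(log_mu)
    theta = config.dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))

    cm = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=samples.index), samples
    )
    truth = SimTruth(
        sex_alt=sex_alt,
        age_alt=age_alt,
        sex_effect=sex_eff,
        age_effect=age_eff,
        region_effects=gamma,
        random_effects=pd.DataFrame(delta, index=genes, columns=individuals),
    )
    return cm, truth


def simulate_linked_signals(
    n_pairs: int,
    n_samples: int,
    target_r: float,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Peak/expression intensity matrices with planted correlated pairs.

    Pair i links peak i with gene i through a shared standard-normal latent
    factor so that corr(peak_i, gene_i) = target_r in expectation; all cross
    pairs are independent.  Returns (peaks, expression, truth) where truth
    lists the planted (peak_id, gene_id, target_r) rows.
    """
    if n_samples < 4:
        raise InvalidConfigError("n_samples must be >= 4")
    if not -1.0 < target_r < 1.0:
        raise InvalidConfigError("target_r must lie strictly in (-1, 1)")
    rng = np.random.default_rng(seed)
    factor = rng.normal(size=(n_pairs, n_samples))
    peaks = factor + 0.0
    expr = target_r * factor + math.sqrt(1.0 - target_r**2) * rng.normal(
        size=(n_pairs, n_samples)
    )
    peaks = noise_sd * peaks
    expr = noise_sd * expr
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    peak_ids = [f"peak{i:05d}" for i in range(n_pairs)]
    gene_ids = [f"gene{i:05d}" for i in range(n_pairs)]
    truth = pd.DataFrame(
        {"peak_id": peak_ids, "gene_id": gene_ids, "target_r": target_r}
    )
    return (
        pd.DataFrame(peaks, index=peak_ids, columns=sample_ids),
        pd.DataFrame(expr, index=gene_ids, columns=sample_ids),
        truth,
    )


# ---------------------------------------------------------------------------
# Toy annotations with controlled exact-match structure
# ---------------------------------------------------------------------------

_EXON_LEN = 200
_INTRON_LEN = 300
_LOCUS_GAP = 5_000
_SHIFT = 7  # bp offset used to break an exact coordinate match


def _make_transcript(tid: str, gene: str, chrom: str, start: int,
                     strand: str = "+", n_exons: int = 3) -> TranscriptModel:
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append((pos, pos + _EXON_LEN))
        pos += _EXON_LEN + _INTRON_LEN
    return TranscriptModel(tid, gene, chrom, strand, exons)


# A 3-exon transcript has six boundary coordinates b0..b5 (start/end of each
# exon).  An exon is an exact match iff both its boundaries are unchanged;
# an intron iff both flanking inner boundaries (b1,b2) or (b3,b4) are.
# Breaking a chosen subset of boundaries therefore realizes any per-
# transcript (matched exons, matched introns) pair except (3,<2) and (0,2),
# which are structurally impossible because intact introns pin the inner
# boundaries of the middle exon.
_BREAKS: dict[tuple[int, int], tuple[int, ...]] = {
    (3, 2): (),
    (2, 2): (0,),
    (2, 1): (2,),
    (2, 0): (2, 3),
    (1, 2): (0, 5),
    (1, 1): (0, 2),
    (1, 0): (0, 2, 3),
    (0, 1): (0, 3, 5),
    (0, 0): (0, 2, 3, 5),
}


def _break_pattern(ref: TranscriptModel, tid: str,
                   pattern: tuple[int, int]) -> TranscriptModel:
    """Derive an assembled transcript matching ``pattern`` exons/introns."""
    bounds = [c for exon in ref.exons for c in exon]  # b0..b5
    for b in _BREAKS[pattern]:
        bounds[b] += _SHIFT
    exons = [(bounds[2 * j], bounds[2 * j + 1]) for j in range(3)]
    return TranscriptModel(tid, tid, ref.chrom, ref.strand, exons)


def _pattern_mix(n: int, target_exons: int, target_introns: int
                 ) -> list[tuple[int, int]]:
    """Per-transcript (exon, intron) match targets summing to the globals.

    Uses ``n_full`` exact copies (3,2) plus partial transcripts with exon
    matches in {0,1,2} and intron matches in {0,1,2}, pairing the largest
    residual intron counts with nonzero exon counts so the impossible (0,2)
    combination never arises.  Raises when no integer mix exists.
    """
    E, I = target_exons, target_introns
    for n_full in range(min(n, E // 3, I // 2), -1, -1):
        m = n - n_full
        ep, ip = E - 3 * n_full, I - 2 * n_full
        if not (0 <= ep <= 2 * m and 0 <= ip <= 2 * m):
            continue
        n_i2 = max(0, ip - m)              # slots forced to 2 intron matches
        n_e_nonzero = min(m, ep)
        if n_i2 > n_e_nonzero:             # would need a (0,2) transcript
            continue
        t_e = max(0, ep - m)
        e_list = [2] * t_e + [1] * (ep - 2 * t_e)
        e_list += [0] * (m - len(e_list))
        i_list = [2] * n_i2 + [1] * (ip - 2 * n_i2)
        i_list += [0] * (m - len(i_list))
        mix = [(3, 2)] * n_full + list(zip(sorted(e_list, reverse=True),
                                           sorted(i_list, reverse=True)))
        assert sum(e for e, _ in mix) == E and sum(i for _, i in mix) == I
        return mix
    raise InvalidConfigError(
        f"exon/intron match targets ({E}, {I}) over {n} assembled "
        "transcripts are not jointly realizable with 3-exon transcripts"
    )


def simulate_annotations(
    n_ref_tx: int,
    n_asm_tx: int,
    exon_match_frac: float,
    intron_match_frac: float,
    seed: int = 0,
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Reference and assembled transcript sets with planted match fractions.

    The first min(n_ref_tx, n_asm_tx) assembled transcripts are derived from
    reference transcripts with deterministic boundary breaks chosen so the
    exon- and intron-level exact-match sensitivity of the assembled set
    equals the configured fractions (up to one transcript's granularity);
    surplus assembled transcripts are placed in fresh intergenic loci and
    lower precision only.
    """
    if not (0.0 <= exon_match_frac <= 1.0 and 0.0 <= intron_match_frac <= 1.0):
        raise InvalidConfigError("match fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    reference = []
    pos = 1_000
    for i in range(n_ref_tx):
        strand = "+" if i % 2 == 0 else "-"
        reference.append(
            _make_transcript(f"ref{i:05d}", f"refg{i:05d}", chrom, pos, strand)
        )
        pos = reference[-1].end + _LOCUS_GAP

    n_derived = min(n_ref_tx, n_asm_tx)
    mix = _pattern_mix(
        n_derived,
        round(exon_match_frac * 3 * n_ref_tx),
        round(intron_match_frac * 2 * n_ref_tx),
    )
    order = rng.permutation(n_derived)
    assembled = [
        _break_pattern(reference[order[i]], f"asm{i:05d}", mix[i])
        for i in range(n_derived)
    ]
    for j in range(n_derived, n_asm_tx):  # novel loci, no ref overlap
        assembled.append(
            _make_transcript(f"asm{j:05d}", f"asm{j:05d}", chrom, pos, "+")
        )
        pos = assembled[-1].end + _LOCUS_GAP
    return reference, assembled
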