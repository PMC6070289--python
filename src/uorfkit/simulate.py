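"""Synthetic transcriptomes, count tables, and strain populations.

The generator emulates the statistical structure the downstream analysis
assumes: transcripts carrying planted AUG-initiated uORFs of controlled
Kozak strength; mRNA and ribosome-footprint (RPF) counts drawn from
negative-binomial distributions with a mean–dispersion trend
``phi(mu) = a0 + a1/mu`` and two replicates for a designated sample pair;
and populations of strains segregating AUG-creating mutations with a
planted adaptive fraction alpha.

Counts are generated per feature directly; per-position P-site coverage,
when needed, is derived by multinomial scatter across the feature.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from uorfkit.annotate import DEFAULT_KOZAK_WINDOW, KozakPPM
from uorfkit.models import STOP_CODONS, TranscriptModel, UORF

_BASES = np.array(list("ACGT"))


@dataclass
class PopGenConfig:
    """Parameters of the strain-population simulator."""

    n_strains: int = 84
    n_test_sites: int = 2000
    n_neutral_sites: int = 2000
    alpha_true: float = 0.5
    #: 'neutral' — test-class polymorphism shares the neutral SFS;
    #: 'deleterious' — an extra low-frequency polymorphic class is planted
    #: in the test region, biasing the original MK estimator downward.
    daf_model: str = "neutral"
    #: probability that a site is a fixed difference (before the adaptive
    #: inflation of the test class)
    p_fixed: float = 0.3
    #: weight of the deleterious polymorphic class relative to the neutral
    #: polymorphic weight (daf_model='deleterious' only)
    deleterious_weight: float = 0.6


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator.

    Identical seed + config gives byte-identical outputs.  Dispersion follows
    ``phi(mu) = a0 + a1/mu`` with ``dispersion_params = (a0, a1)``.
    Log-normal parameters are (mean, sd) of the natural log.
    """

    seed: int = 0
    n_genes: int = 200
    utr5_length_dist: tuple[int, int] = (100, 300)
    gc_content: float = 0.43
    uorf_rate: float = 1.5
    dispersion_params: tuple[float, float] = (0.05, 5.0)
    mean_expression_dist: tuple[float, float] = (5.0, 1.2)
    te_cds_dist: tuple[float, float] = (0.0, 0.5)
    te_uorf_dist: tuple[float, float] = (-1.0, 0.8)
    uorf_repression_effect: float = 0.8
    p_untranslated_uorf: float = 0.1
    n_samples: int = 12
    replicate_samples: tuple[str, ...] = ("s01", "s02")
    uorf_kozak_target: float | None = None
    popgen: PopGenConfig = field(default_factory=PopGenConfig)

    def __post_init__(self) -> None:
        a0, a1 = self.dispersion_params
        if a0 < 0 or a1 < 0:
            raise ValueError("dispersion_params components must be >= 0")
        lo, hi = self.utr5_length_dist
        if not (0 < lo <= hi):
            raise ValueError("invalid 5'UTR length bounds")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if isinstance(self.popgen, dict):
            self.popgen = PopGenConfig(**self.popgen)

    @property
    def sample_names(self) -> list[str]:
        return [f"s{i + 1:02d}" for i in range(self.n_samples)]

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream: independent generator derived from the root seed."""
        key = zlib.crc32(stream.encode()) % 2**31
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))

    def dispersion(self, mu: np.ndarray | float) -> np.ndarray | float:
        a0, a1 = self.dispersion_params
        return a0 + a1 / np.maximum(mu, 1e-12)


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators."""

    planted_uorfs: list[UORF] = field(default_factory=list)
    #: feature_id -> mean mRNA abundance (before size factors)
    mu: dict[str, float] = field(default_factory=dict)
    #: (feature_id, sample) -> true TE
    te: dict[tuple[str, str], float] = field(default_factory=dict)
    #: library key (sample, assay, replicate) -> planted size factor
    size_factors: dict[tuple[str, str, int], float] = field(default_factory=dict)
    alpha_true: float | None = None


# ---------------------------------------------------------------------------
# Kozak-context planting
# ---------------------------------------------------------------------------

def default_kozak_ppm(window=DEFAULT_KOZAK_WINDOW, strength: float = 0.55) -> KozakPPM:
    """A synthetic, informative reference PPM for context planting and tests.

    Each position favors one base (A at -3/-2/-1, C elsewhere upstream, G at
    +4, in the spirit of metazoan initiation contexts) with probability
    ``strength``, the rest uniform.
    """
    favored = {-6: "C", -5: "C", -4: "A", -3: "A", -2: "A", -1: "C", 3: "G"}
    rows = []
    for rel in window:
        row = np.full(4, (1 - strength) / 3)
        row["ACGT".index(favored.get(rel, "A"))] = strength
        rows.append(row)
    return KozakPPM(np.array(rows), tuple(window))


def plant_kozak_context(ppm: KozakPPM, target_score: float) -> tuple[str, float]:
    """Context string whose Kozak score is as close as possible to ``target_score``.

    The achievable scores form a finite grid (one log-odds term per window
    position and base); exhaustive enumeration picks the closest combination,
    so the achieved score equals the target within the grid resolution.
    """
    per_pos = np.log2(np.maximum(ppm.matrix, 1e-300) / 0.25)
    best_combo, best_err = None, np.inf
    for combo in itertools.product(range(4), repeat=len(ppm.window)):
        s = sum(per_pos[i, j] for i, j in enumerate(combo))
        if abs(s - target_score) < best_err:
            best_err, best_combo, best_score = abs(s - target_score), combo, s
    return "".join("ACGT"[j] for j in best_combo), float(best_score)


# ---------------------------------------------------------------------------
# Transcriptome generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _random_nonstop_codon(rng: np.random.Generator, gc: float) -> str:
    while True:
        codon = "".join(_random_seq(rng, 3, gc))
        if codon not in STOP_CODONS:
            return codon


def generate_transcriptome(
    config: SimulationConfig,
) -> tuple[list[TranscriptModel], SyntheticTruth]:
    """Generate transcripts with planted uORFs and record the ground truth.

    Each transcript has a random 5'UTR, a valid CDS (ATG ... stop, no internal
    in-frame stops), and a 3'UTR.  ``Poisson(uorf_rate)`` uORFs are planted per
    transcript at non-overlapping 5'UTR positions; when
    ``config.uorf_kozak_target`` is set, the context bases around each planted
    uAUG are chosen from the reference PPM to hit that score.
    """
    rng = config.rng("transcriptome")
    ppm = default_kozak_ppm()
    truth = SyntheticTruth()
    transcripts = []
    for g in range(config.n_genes):
        gene_id = f"g{g + 1:04d}"
        tid = f"{gene_id}.t1"
        utr5_len = int(rng.integers(config.utr5_length_dist[0], config.utr5_length_dist[1] + 1))
        n_codons = int(rng.integers(60, 301))
        utr3_len = int(rng.integers(50, 201))
        utr5 = _random_seq(rng, utr5_len, config.gc_content)
        cds = "ATG" + "".join(
            _random_nonstop_codon(rng, config.gc_content) for _ in range(n_codons - 2)
        ) + STOP_CODONS[rng.integers(3)]
        utr3 = _random_seq(rng, utr3_len, config.gc_content)
        seq = np.concatenate([utr5, np.array(list(cds)), utr3])
        cds_start, cds_end = utr5_len, utr5_len + 3 * n_codons

        n_uorfs = rng.poisson(config.uorf_rate)
        placed: list[tuple[int, int]] = []
        for _ in range(n_uorfs):
            m = int(rng.integers(3, 11))  # codons incl. start and stop
            length = 3 * m
            lo, hi = 7, utr5_len - length
            if hi <= lo:
                continue
            for _attempt in range(20):
                s = int(rng.integers(lo, hi))
                # 7 nt margin keeps Kozak-context planting off neighbors
                if all(s + length + 7 <= a or s >= b + 7 for a, b in placed):
                    break
            else:
                continue
            placed.append((s, s + length))
            codons = ["ATG"] + [
                _random_nonstop_codon(rng, config.gc_content) for _ in range(m - 2)
            ] + [STOP_CODONS[rng.integers(3)]]
            seq[s : s + length] = list("".join(codons))
            achieved = None
            if config.uorf_kozak_target is not None:
                ctx, achieved = plant_kozak_context(ppm, config.uorf_kozak_target)
                for rel, base in zip(ppm.window, ctx):
                    p = s + rel
                    if 0 <= p < cds_start:
                        seq[p] = base
                # repair if planting the +4 base turned codon 2 into a stop
                if "".join(seq[s + 3 : s + 6]) in STOP_CODONS:
                    seq[s + 4] = "C"
            truth.planted_uorfs.append(
                UORF(
                    transcript_id=tid,
                    start=s,
                    end=s + length,
                    kozak_score=achieved,
                    distance_uaug_to_caug=cds_start - s,
                    distance_cap_to_uaug=s,
                    distance_stop_to_caug=cds_start - (s + length),
                    planted=True,
                )
            )
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                sequence="".join(seq),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return transcripts, truth


# ---------------------------------------------------------------------------
# Count generation
# ---------------------------------------------------------------------------

def sample_nb(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Negative-binomial draws with mean ``mean`` and dispersion ``phi``
    (variance mean + phi * mean^2); Poisson in the phi -> 0 limit."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    poisson_like = pos & (phi < 1e-8)
    out[poisson_like] = rng.poisson(mean[poisson_like])
    nb = pos & ~poisson_like
    n = 1.0 / phi[nb]
    p = 1.0 / (1.0 + phi[nb] * mean[nb])
    out[nb] = rng.negative_binomial(n, p)
    return out


def generate_counts(
    transcripts: list[TranscriptModel],
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Per-sample mRNA and RPF count tables for CDSs and planted uORFs.

    Long format: feature_id, sample, replicate, assay in {mrna, rpf}, count.
    mRNA counts ~ NB(mu * size_factor, phi(mu)); RPF counts ~ NB(TE * mu *
    size_factor, phi(.)).  Size factors are drawn log-uniform in [0.5, 2]
    per library and recorded in the truth, as are per-feature mu and TE.
    """
    rng = config.rng("counts")
    planted_by_tid: dict[str, list[UORF]] = {}
    for u in truth.planted_uorfs:
        planted_by_tid.setdefault(u.transcript_id, []).append(u)

    features: list[tuple[str, float, float]] = []  # (feature_id, mu, base_te)
    for t in transcripts:
        mu = float(rng.lognormal(*config.mean_expression_dist))
        uorfs = planted_by_tid.get(t.transcript_id, [])
        n_translated = 0
        uorf_tes = []
        for u in uorfs:
            if rng.random() < config.p_untranslated_uorf:
                uorf_tes.append(0.0)
            else:
                uorf_tes.append(float(rng.lognormal(*config.te_uorf_dist)))
                n_translated += 1
        te_cds = float(rng.lognormal(*config.te_cds_dist)) * (
            config.uorf_repression_effect ** n_translated
        )
        features.append((f"{t.transcript_id}:CDS", mu, te_cds))
        for u, te_u in zip(uorfs, uorf_tes):
            features.append((u.feature_id, mu, te_u))

    rows = []
    for sample in config.sample_names:
        n_reps = 2 if sample in config.replicate_samples else 1
        for rep in range(1, n_reps + 1):
            sf = {a: float(np.exp(rng.uniform(np.log(0.5), np.log(2.0)))) for a in ("mrna", "rpf")}
            truth.size_factors[(sample, "mrna", rep)] = sf["mrna"]
            truth.size_factors[(sample, "rpf", rep)] = sf["rpf"]
            mu_vec = np.array([mu for _, mu, _ in features])
            te_vec = np.array([te for _, _, te in features])
            m_mean = mu_vec * sf["mrna"]
            r_mean = te_vec * mu_vec * sf["rpf"]
            m_counts = sample_nb(rng, m_mean, config.dispersion(m_mean))
            r_counts = sample_nb(rng, r_mean, config.dispersion(np.maximum(r_mean, 1e-12)))
            for (fid, mu, te), km, kr in zip(features, m_counts, r_counts):
                rows.append((fid, sample, rep, "mrna", int(km)))
                rows.append((fid, sample, rep, "rpf", int(kr)))
    for fid, mu, te in features:
        truth.mu[fid] = mu
        for sample in config.sample_names:
            truth.te[(fid, sample)] = te
    return pd.DataFrame(rows, columns=["feature_id", "sample", "replicate", "assay", "count"])


def scatter_coverage(
    rng: np.random.Generator, total_count: int, length: int
) -> np.ndarray:
    """Optional per-position coverage: multinomial scatter of a feature's
    count across its positions, uniform by default."""
    return rng.multinomial(total_count, np.full(length, 1.0 / length))


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------

def _sfs_weights(n: int, model: str) -> np.ndarray:
    i = np.arange(1, n)
    if model == "neutral":
        w = 1.0 / i
    elif model == "deleterious":
        # neutral 1/i weights shifted toward low frequency
        w = np.exp(-i / (0.08 * n)) / i
    else:
        raise ValueError(f"unknown DAF model {model!r}")
    return w / w.sum()


def generate_population(config: SimulationConfig) -> pd.DataFrame:
    """Fixed and polymorphic AUG-creating sites for a test (5'UTR) and a
    neutral (short-intron) region class.

    The fixed count of the test class is inflated by 1/(1 - alpha_true)
    relative to neutrality, so the expected original-MK alpha of the test
    class equals ``alpha_true`` while the neutral class has alpha 0 by
    construction.  Under ``daf_model='deleterious'`` an additional
    low-frequency polymorphic class is planted in the test region only.
    """
    pg = config.popgen
    if pg.n_strains < 2:
        raise ValueError("n_strains must be >= 2")
    if not 0.0 <= pg.alpha_true < 1.0:
        raise ValueError("alpha_true must be in [0, 1)")
    rng = config.rng("population")
    n = pg.n_strains
    neutral_w = _sfs_weights(n, "neutral")
    deleterious_w = _sfs_weights(n, "deleterious")
    i_vals = np.arange(1, n)
    frames = []

    def emit(region, n_sites, weights):
        probs = np.array(weights, dtype=float)
        probs = probs / probs.sum()
        kinds = rng.choice(len(probs), size=n_sites, p=probs)
        derived = np.full(n_sites, n, dtype=int)
        for kind, w in ((1, neutral_w), (2, deleterious_w)):
            mask = kinds == kind
            derived[mask] = rng.choice(i_vals, size=int(mask.sum()), p=w)
        frames.append(
            pd.DataFrame(
                {
                    "site_id": [f"{region}_{k + 1:06d}" for k in range(n_sites)],
                    "class": region,
                    "status": np.where(kinds == 0, "fixed", "polymorphic"),
                    "derived_count": derived,
                    "total_alleles": n,
                    "change": "gain",
                }
            )
        )

    d_weight = pg.deleterious_weight if pg.daf_model == "deleterious" else 0.0
    emit("intron", pg.n_neutral_sites, [pg.p_fixed, 1 - pg.p_fixed, 0.0])
    emit(
        "utr5",
        pg.n_test_sites,
        [pg.p_fixed / (1.0 - pg.alpha_true), 1 - pg.p_fixed, (1 - pg.p_fixed) * d_weight],
    )
    return pd.concat(frames, ignore_index=True)
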