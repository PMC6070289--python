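"""McDonald–Kreitman style selection tests on AUG-creating mutations.

Gains and losses of AUG triplets are polarized by parsimony against two
outgroups; fixed and polymorphic counts in a test region (5'UTR uAUGs) are
contrasted with a neutral control (positions 8-30 of short introns) to
estimate the adaptive fraction alpha of fixations, by the original MK
estimator (alpha_ori = 1 - D_SI*P_RI / (P_SI*D_RI), with a minor-allele-
frequency floor on polymorphisms) and by the asymptotic extrapolation of
alpha over derived allele frequency.  Fixed counts can be corrected for
multiple substitutions with Kimura's two-parameter model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class TripletSite:
    """One AUG-triplet site: per-strain ingroup states plus two outgroups.

    States are True where the triplet is ATG; ``None`` marks missing strain
    calls (frequencies are computed over non-missing alleles).
    """

    site_id: str
    region_class: str
    ingroup_is_atg: Sequence[bool | None]
    outgroup1_is_atg: bool | None
    outgroup2_is_atg: bool | None
    uorf_class: str = "none"


@dataclass
class PolarizedMutation:
    site_id: str
    direction: str  # gain | loss
    status: str  # fixed | polymorphic
    lineage: str  # ingroup | outgroup1
    derived_allele_frequency: float
    region_class: str = ""

    def __post_init__(self) -> None:
        if self.status == "fixed" and self.derived_allele_frequency != 1.0:
            raise ValueError("fixed mutations must have DAF 1 in the ingroup sample")


def polarize_triplet(site: TripletSite) -> PolarizedMutation | None:
    """Parsimony polarization of one site against the two outgroups.

    Both outgroups non-ATG and any ingroup ATG: a gain on the ingroup
    lineage, fixed if every strain carries the ATG, else polymorphic with
    DAF equal to the ATG fraction.  Ingroup ATG with outgroup1 non-ATG but
    outgroup2 ATG: a loss on the outgroup1 lineage.  Discordant or
    uninformative patterns (including missing outgroups) return ``None``.
    """
    if site.outgroup1_is_atg is None or site.outgroup2_is_atg is None:
        return None
    states = [s for s in site.ingroup_is_atg if s is not None]
    if len(states) < 1:
        return None
    n_atg = sum(states)
    if not site.outgroup1_is_atg and not site.outgroup2_is_atg:
        if n_atg == 0:
            return None
        fixed = n_atg == len(states)
        return PolarizedMutation(
            site_id=site.site_id,
            direction="gain",
            status="fixed" if fixed else "polymorphic",
            lineage="ingroup",
            derived_allele_frequency=1.0 if fixed else n_atg / len(states),
            region_class=site.region_class,
        )
    if not site.outgroup1_is_atg and site.outgroup2_is_atg and n_atg == len(states):
        return PolarizedMutation(
            site_id=site.site_id,
            direction="loss",
            status="fixed",
            lineage="outgroup1",
            derived_allele_frequency=1.0,
            region_class=site.region_class,
        )
    return None


# ---------------------------------------------------------------------------
# Site-frequency spectra
# ---------------------------------------------------------------------------

def daf_spectrum(
    derived_counts: Sequence[int],
    total_alleles: Sequence[int] | int,
    n_bins: int | None = None,
    project_n: int | None = None,
) -> np.ndarray:
    """Derived-allele-frequency spectrum of polymorphic sites.

    Without projection, returns counts per DAF bin (``n_bins`` equal-width
    bins over (0, 1)).  With ``project_n`` m, each site with d derived out
    of n alleles contributes its expected hypergeometric mass over 0..m
    derived in a sample of m drawn without replacement; sites with fewer
    than m alleles are excluded.  Projection to the original n is the
    identity (up to the counts-vs-mass representation).
    """
    d = np.asarray(derived_counts, dtype=int)
    n = np.broadcast_to(np.asarray(total_alleles, dtype=int), d.shape)
    if project_n is not None:
        m = int(project_n)
        sfs = np.zeros(m + 1)
        for di, ni in zip(d, n):
            if ni < m:
                continue
            j = np.arange(0, m + 1)
            sfs += stats.hypergeom.pmf(j, ni, di, m)
        return sfs
    if n_bins is None:
        raise ValueError("either n_bins or project_n is required")
    daf = d / n
    hist, _ = np.histogram(daf, bins=np.linspace(0, 1, n_bins + 1))
    return hist


# ---------------------------------------------------------------------------
# K80 correction
# ---------------------------------------------------------------------------

def k80_distance(transition_fraction: float, transversion_fraction: float) -> float:
    """Kimura two-parameter distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)."""
    P, Q = float(transition_fraction), float(transversion_fraction)
    if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
        raise ValueError("substitution saturation: K80 distance undefined")
    return -0.5 * np.log(1 - 2 * P - Q) - 0.25 * np.log(1 - 2 * Q)


def k80_adjust(raw_fixed_count: float, transition_fraction: float,
               transversion_fraction: float) -> float:
    """Multiple-hit corrected fixed count: raw * d / (P + Q).

    The region-wide transition (P) and transversion (Q) fractions give the
    per-site correction factor; the factor tends to 1 as divergence
    vanishes.
    """
    P, Q = float(transition_fraction), float(transversion_fraction)
    if P + Q == 0:
        return float(raw_fixed_count)
    return float(raw_fixed_count) * k80_distance(P, Q) / (P + Q)


# ---------------------------------------------------------------------------
# MK estimators
# ---------------------------------------------------------------------------

@dataclass
class MKTable:
    """Fixed/polymorphic counts for a test region and its neutral control.

    Polymorphic sites carry their derived allele frequencies so that MAF
    filtering and frequency binning operate on the same object.
    """

    d_ri: float
    d_si: float
    p_ri_daf: np.ndarray = field(default_factory=lambda: np.array([]))
    p_si_daf: np.ndarray = field(default_factory=lambda: np.array([]))
    k80_factor_ri: float = 1.0
    k80_factor_si: float = 1.0

    @staticmethod
    def from_site_table(sites: pd.DataFrame, test_class: str = "utr5",
                        neutral_class: str = "intron",
                        change: str = "gain") -> "MKTable":
        """Build from a long site table (class, status, derived_count,
        total_alleles, change) as written by the population simulator."""
        s = sites[sites["change"] == change] if "change" in sites else sites

        def split(cls):
            sub = s[s["class"] == cls]
            fixed = float((sub["status"] == "fixed").sum())
            poly = sub[sub["status"] == "polymorphic"]
            return fixed, (poly["derived_count"] / poly["total_alleles"]).to_numpy()

        d_ri, p_ri = split(test_class)
        d_si, p_si = split(neutral_class)
        return MKTable(d_ri=d_ri, d_si=d_si, p_ri_daf=p_ri, p_si_daf=p_si)

    def polymorphic_counts(self, maf_threshold: float = 0.0) -> tuple[float, float]:
        def count(daf):
            maf = np.minimum(daf, 1.0 - daf)
            return float((maf >= maf_threshold).sum())

        return count(self.p_ri_daf), count(self.p_si_daf)


def alpha_from_counts(d_si: float, p_si: float, d_ri: float, p_ri: float) -> float:
    """alpha_ori = 1 - (D_SI * P_RI) / (P_SI * D_RI)."""
    if p_si <= 0 or d_ri <= 0:
        raise ValueError("alpha undefined: P_SI and D_RI must be positive")
    return 1.0 - (d_si * p_ri) / (p_si * d_ri)


def alpha_original(table: MKTable, maf_threshold: float = 0.05) -> float:
    """Original MK alpha with polymorphisms filtered at MAF >= threshold and
    K80-adjusted fixed counts."""
    p_ri, p_si = table.polymorphic_counts(maf_threshold)
    return alpha_from_counts(
        table.d_si * table.k80_factor_si, p_si, table.d_ri * table.k80_factor_ri, p_ri
    )


@dataclass
class AsymptoticFit:
    bin_mid_daf: np.ndarray
    alpha_at_daf: np.ndarray
    params: tuple[float, ...]
    alpha_asym: float
    fit_mode: str  # exponential | linear-fallback
    merged_bins: int = 0
    ci: tuple[float, float] | None = None


def asymptotic_mk(
    table: MKTable,
    n_bins: int = 10,
    daf_range: tuple[float, float] = (0.05, 0.95),
) -> AsymptoticFit:
    """Asymptotic MK estimate: alpha(x) per derived-allele-frequency bin,
    extrapolated to x = 1 with alpha(x) = a + b*exp(-c*x).

    Neutral polymorphisms define equal-size frequency bins; the same break
    points bin the test polymorphisms.  Only bins with mid-frequency inside
    ``daf_range`` are fitted; bins left empty on the neutral side are merged
    with their left neighbor.  If the exponential fit fails to converge, a
    linear fit in x is used and reported as the fallback.
    """
    d_ri = table.d_ri * table.k80_factor_ri
    d_si = table.d_si * table.k80_factor_si
    if d_ri <= 0 or len(table.p_si_daf) == 0:
        raise ValueError("asymptotic MK needs fixed test counts and neutral polymorphism")
    qs = np.quantile(table.p_si_daf, np.linspace(0, 1, n_bins + 1))
    breaks = np.unique(qs)
    merged = (n_bins + 1) - len(breaks)
    breaks[0], breaks[-1] = 0.0, 1.0 + 1e-9
    idx_si = np.digitize(table.p_si_daf, breaks) - 1
    idx_ri = np.digitize(table.p_ri_daf, breaks) - 1
    n_eff = len(breaks) - 1
    xs, alphas = [], []
    for b in range(n_eff):
        p_si_b = float((idx_si == b).sum())
        p_ri_b = float((idx_ri == b).sum())
        if p_si_b == 0:
            merged += 1
            continue
        x_b = float(table.p_si_daf[idx_si == b].mean())
        if not daf_range[0] <= x_b <= daf_range[1]:
            continue
        xs.append(x_b)
        alphas.append(1.0 - (d_si / d_ri) * (p_ri_b / p_si_b))
    xs_a, al_a = np.array(xs), np.array(alphas)
    if len(xs_a) < 2:
        raise ValueError("fewer than 2 usable frequency bins")

    lin = np.polyfit(xs_a, al_a, 1)
    if len(xs_a) >= 3:
        try:
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    lambda x, a, b, c: a + b * np.exp(-c * x),
                    xs_a, al_a,
                    p0=(float(al_a[-1]), float(al_a[0] - al_a[-1]), 1.0),
                    maxfev=10000,
                )
            a, b, c = (float(v) for v in popt)
            return AsymptoticFit(xs_a, al_a, (a, b, c),
                                 alpha_asym=a + b * np.exp(-c),
                                 fit_mode="exponential", merged_bins=merged)
        except RuntimeError:
            pass
    return AsymptoticFit(xs_a, al_a, (float(lin[1]), float(lin[0])),
                         alpha_asym=float(np.polyval(lin, 1.0)),
                         fit_mode="linear-fallback", merged_bins=merged)


def bootstrap_alpha(
    table: MKTable,
    estimator: Callable[[MKTable], float],
    n_reps: int = 1000,
    seed: int = 0,
    stratify: str = "status",
) -> tuple[float, float, float]:
    """Percentile bootstrap over sites: the estimator is recomputed on
    resampled site sets and the median with the 2.5% and 97.5% quantiles
    returned.

    ``stratify='status'`` (default) resamples each of the four site classes
    (fixed and polymorphic, test and neutral) separately with replacement;
    fixed sites are exchangeable, so the fixed counts carry over unchanged
    and the interval reflects polymorphism sampling only.
    ``stratify='region'`` resamples all sites of a region class jointly, so
    the fixed/polymorphic split varies per replicate and the interval also
    carries the fixed-count sampling variance (giving near-nominal coverage
    against independent re-simulations).

    Raises if the estimator is undefined in more than half the replicates.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    if stratify not in ("status", "region"):
        raise ValueError("stratify must be 'status' or 'region'")
    rng = np.random.default_rng(seed)

    def resample_poly(daf):
        return rng.choice(daf, size=len(daf), replace=True) if len(daf) else daf

    values = []
    for _ in range(n_reps):
        if stratify == "status":
            rep = MKTable(
                d_ri=table.d_ri,
                d_si=table.d_si,
                p_ri_daf=resample_poly(table.p_ri_daf),
                p_si_daf=resample_poly(table.p_si_daf),
                k80_factor_ri=table.k80_factor_ri,
                k80_factor_si=table.k80_factor_si,
            )
        else:
            reps = {}
            for key, d_count, daf in (
                ("ri", table.d_ri, table.p_ri_daf),
                ("si", table.d_si, table.p_si_daf),
            ):
                # pool fixed sites (DAF sentinel 1.0+) with polymorphic ones
                pool = np.concatenate([np.full(int(round(d_count)), 2.0), daf])
                draw = rng.choice(pool, size=len(pool), replace=True)
                reps[key] = (float((draw == 2.0).sum()), draw[draw < 2.0])
            rep = MKTable(
                d_ri=reps["ri"][0], d_si=reps["si"][0],
                p_ri_daf=reps["ri"][1], p_si_daf=reps["si"][1],
                k80_factor_ri=table.k80_factor_ri,
                k80_factor_si=table.k80_factor_si,
            )
        try:
            values.append(float(estimator(rep)))
        except (ValueError, ZeroDivisionError):
            continue
    if len(values) < n_reps / 2:
        raise ValueError("estimator undefined in more than half of the replicates")
    v = np.asarray(values)
    return (float(np.median(v)), float(np.quantile(v, 0.025)), float(np.quantile(v, 0.975)))
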