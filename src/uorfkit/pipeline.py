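"""End-to-end orchestration: simulate -> annotate -> quantify -> test -> MK.

Every stage writes TSV outputs plus a JSON manifest recording the seed, the
thresholds applied, and the record counts passing each filter.  Reruns with
an identical configuration produce identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from uorfkit import annotate, io, popgen, te_stats
from uorfkit.simulate import SimulationConfig, generate_counts, generate_population, \
    generate_transcriptome

#: Translational-breadth classes for a 12-sample design: a uORF translated
#: (TE >= 0.5) in >= 11 samples is Class I, in 5-10 Class II, in 1-4 Class
#: III; expressed but never translated is Class IV.
CLASS_BREAKS = (11, 5, 1)


@dataclass
class RunConfig:
    """Thresholds and paths for a full pipeline run.

    Defaults follow the analysis conventions: a feature is expressed at
    mRNA RPKM >= 1, well-transcribed at normalized mRNA count >= 30,
    translated at TE >= 0.1 (weak) or >= 0.5 (standard); FDR 0.05 for the
    Wald tests and MAF >= 0.05 for MK polymorphisms.
    """

    out_dir: str = "uorfkit_run"
    seed: int = 0
    rpkm_min: float = 1.0
    norm_mrna_min: float = 30.0
    te_tiers: tuple[float, ...] = (0.1, 0.5)
    fdr: float = 0.05
    maf: float = 0.05
    mk_bootstrap_reps: int = 1000
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        if 0.5 not in self.te_tiers:
            raise ValueError(
                "translational-breadth classes need the 0.5 TE tier; "
                f"got te_tiers={self.te_tiers}"
            )


def assign_breadth_class(n_translated: int, expressed: bool,
                         breaks: tuple[int, int, int] = CLASS_BREAKS) -> str | None:
    """Class I-IV from the number of samples where the uORF is translated."""
    if not expressed:
        return None
    if n_translated >= breaks[0]:
        return "I"
    if n_translated >= breaks[1]:
        return "II"
    if n_translated >= breaks[2]:
        return "III"
    return "IV"


def _feature_lengths(transcripts, uorfs) -> dict[str, int]:
    lengths = {}
    by_tid = {t.transcript_id: t for t in transcripts}
    for t in transcripts:
        lengths[f"{t.transcript_id}:CDS"] = t.cds_end - t.cds_start
    for u in uorfs:
        t = by_tid[u.transcript_id]
        # uORF-CDS overlap: only the non-CDS portion is counted
        lengths[u.feature_id] = min(u.end, t.cds_start) - u.start
    return lengths


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on synthetic data and return the output manifest."""
    out = io.ensure_dir(config.out_dir)
    sim = config.simulation
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            "rpkm_min": config.rpkm_min,
            "norm_mrna_min": config.norm_mrna_min,
            "te_tiers": list(config.te_tiers),
            "fdr": config.fdr,
            "maf": config.maf,
        },
        "stages": {},
        "warnings": [],
    }
    sim.seed = config.seed

    # --- simulate -----------------------------------------------------------
    transcripts, truth = generate_transcriptome(sim)
    counts = generate_counts(transcripts, truth, sim)
    sites = generate_population(sim)
    io.write_transcripts_fasta(transcripts, out / "transcripts.fa")
    io.write_transcripts_gff3(transcripts, out / "transcripts.gff3")
    io.write_counts(counts, out / "counts.tsv")
    io.write_sites(sites, out / "sites.tsv")
    manifest["stages"]["simulate"] = {
        "n_transcripts": len(transcripts),
        "n_planted_uorfs": len(truth.planted_uorfs),
        "n_sites": int(len(sites)),
    }

    # --- annotate -----------------------------------------------------------
    ppm = annotate.build_kozak_ppm(transcripts)
    all_uorfs = []
    for t in transcripts:
        us = annotate.scan_uorfs(t)
        annotate.score_uorfs(us, t, ppm)
        all_uorfs.extend(us)
    io.write_uorf_table(all_uorfs, out / "uorfs.tsv")
    planted_keys = {(u.transcript_id, u.start, u.end) for u in truth.planted_uorfs}
    found_keys = {(u.transcript_id, u.start, u.end) for u in all_uorfs}
    manifest["stages"]["annotate"] = {
        "n_uorfs": len(all_uorfs),
        "n_planted_recovered": len(planted_keys & found_keys),
        "n_planted": len(planted_keys),
    }

    # --- quantify -----------------------------------------------------------
    lengths = _feature_lengths(transcripts, all_uorfs)
    counted = counts[counts["feature_id"].isin(lengths)]
    lib_sizes = counted.groupby(["sample", "replicate", "assay"])["count"].sum()
    quant_rows = []
    for (sample, rep), g in counted.groupby(["sample", "replicate"]):
        wide = g.pivot_table(index="feature_id", columns="assay", values="count",
                             aggfunc="sum").fillna(0)
        for fid, row in wide.iterrows():
            L = lengths[fid]
            if L < 1:
                continue
            n_m = lib_sizes[(sample, rep, "mrna")]
            n_r = lib_sizes[(sample, rep, "rpf")]
            rpkm_m = row.get("mrna", 0) / (L * n_m) * 1e9
            rpkm_r = row.get("rpf", 0) / (L * n_r) * 1e9
            quant_rows.append(
                (fid, sample, rep, int(row.get("mrna", 0)), int(row.get("rpf", 0)),
                 rpkm_m, rpkm_r, rpkm_r / rpkm_m if rpkm_m > 0 else np.nan)
            )
    quant = pd.DataFrame(
        quant_rows,
        columns=["feature_id", "sample", "replicate", "count_mrna", "count_rpf",
                 "rpkm_mrna", "rpkm_rpf", "te"],
    )
    quant.to_csv(out / "quant.tsv", sep="\t", index=False)
    manifest["stages"]["quantify"] = {"n_feature_samples": int(len(quant))}

    # --- normalization and dispersion ---------------------------------------
    norm = {}
    for assay in ("mrna", "rpf"):
        wide = counts[counts["assay"] == assay].pivot_table(
            index="feature_id", columns=["sample", "replicate"], values="count"
        ).fillna(0)
        sf = te_stats.size_factors(wide.to_numpy())
        norm[assay] = wide / sf[np.newaxis, :]

    rep_samples = list(sim.replicate_samples)
    trends = {}
    for assay in ("mrna", "rpf"):
        blocks = [norm[assay][s].to_numpy() for s in rep_samples]
        stacked = np.vstack(blocks)
        trends[assay] = te_stats.estimate_dispersion_trend(
            stacked, assay=assay, min_mean=config.norm_mrna_min if assay == "mrna" else 1.0
        )
    manifest["stages"]["dispersion"] = {
        a: {"a0": trends[a].a0, "a1": trends[a].a1} for a in trends
    }

    # --- log2TE / SE: replicates directly, other samples via the SE surface --
    te_tables = {}
    surface_train = []
    for s in rep_samples:
        res = te_stats.estimate_log2te_and_se(
            norm["mrna"][s].to_numpy(), norm["rpf"][s].to_numpy(),
            trends["mrna"], trends["rpf"],
        )
        res.index = norm["mrna"].index
        te_tables[s] = res
        surface_train.append(res)
    train = pd.concat(surface_train)
    surface = te_stats.fit_se_surface(train["log2te"], train["mean_mrna"], train["se"])
    n_clamped = 0
    for s in sim.sample_names:
        if s in te_tables:
            continue
        m = norm["mrna"][(s, 1)].to_numpy()
        r = norm["rpf"][(s, 1)].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            log2te = np.where((m > 0) & (r > 0), np.log2(r / np.maximum(m, 1e-300)), np.nan)
        se, clamped = surface.predict(np.nan_to_num(log2te), np.maximum(m, 1e-12))
        n_clamped += int(clamped.sum())
        te_tables[s] = pd.DataFrame(
            {"log2te": log2te, "se": np.where(np.isfinite(log2te), se, np.nan),
             "mean_mrna": m, "mean_rpf": r},
            index=norm["mrna"].index,
        )
    manifest["stages"]["se_surface"] = {"n_clamped_queries": n_clamped}

    # --- beta tests and breadth classes --------------------------------------
    uorf_ids = [u.feature_id for u in all_uorfs]
    cds_of = {u.feature_id: f"{u.transcript_id}:CDS" for u in all_uorfs}
    beta_frames = []
    for s in sim.sample_names:
        tab = te_tables[s]
        present = [fid for fid in uorf_ids if fid in tab.index and cds_of[fid] in tab.index]
        if not present:
            continue
        u_tab = tab.loc[present]
        c_tab = tab.loc[[cds_of[f] for f in present]]
        well = u_tab["mean_mrna"].to_numpy() >= config.norm_mrna_min
        res = te_stats.wald_test_beta(
            u_tab["log2te"].to_numpy(), c_tab["log2te"].to_numpy(),
            u_tab["se"].to_numpy(), c_tab["se"].to_numpy(),
        )
        res.insert(0, "feature_id", present)
        res.insert(1, "sample", s)
        res["well_transcribed"] = well
        beta_frames.append(res)
    beta = pd.concat(beta_frames, ignore_index=True)
    beta.to_csv(out / "beta_tests.tsv", sep="\t", index=False)

    expressed_counts: dict[str, int] = {}
    translated_counts: dict[str, int] = {}
    for s in sim.sample_names:
        q = quant[(quant["sample"] == s) & (quant["replicate"] == 1)]
        q = q.set_index("feature_id")
        for fid in uorf_ids:
            if fid not in q.index:
                continue
            row = q.loc[fid]
            if row["rpkm_mrna"] >= config.rpkm_min:
                expressed_counts[fid] = expressed_counts.get(fid, 0) + 1
                if np.isfinite(row["te"]) and row["te"] >= 0.5:
                    translated_counts[fid] = translated_counts.get(fid, 0) + 1
    classes = {
        fid: assign_breadth_class(translated_counts.get(fid, 0), True)
        for fid in expressed_counts
    }
    pd.Series(classes, name="breadth_class").rename_axis("feature_id").to_csv(
        out / "breadth_classes.tsv", sep="\t"
    )
    class_tally = pd.Series(classes).value_counts().to_dict()
    manifest["stages"]["classes"] = {
        "n_expressed_uorfs": len(expressed_counts),
        "tally": {str(k): int(v) for k, v in sorted(class_tally.items())},
    }

    # --- gamma tests between consecutive samples ------------------------------
    gamma_summary = []
    for s1, s2 in zip(sim.sample_names, sim.sample_names[1:]):
        t1, t2 = te_tables[s1], te_tables[s2]
        present = [
            fid for fid in uorf_ids
            if fid in t1.index and fid in t2.index
            and np.isfinite(t1.loc[fid, "log2te"]) and np.isfinite(t2.loc[fid, "log2te"])
            and np.isfinite(t1.loc[cds_of[fid], "log2te"])
            and np.isfinite(t2.loc[cds_of[fid], "log2te"])
        ]
        if not present:
            continue
        cds_ids = [cds_of[f] for f in present]
        bu = te_stats.wald_test_beta_u(
            t1.loc[present, "log2te"].to_numpy(), t2.loc[present, "log2te"].to_numpy(),
            t1.loc[present, "se"].to_numpy(), t2.loc[present, "se"].to_numpy(),
        )
        gm = te_stats.wald_test_gamma(
            t1.loc[present, "log2te"].to_numpy(), t1.loc[cds_ids, "log2te"].to_numpy(),
            t2.loc[present, "log2te"].to_numpy(), t2.loc[cds_ids, "log2te"].to_numpy(),
            t1.loc[present, "se"].to_numpy(), t1.loc[cds_ids, "se"].to_numpy(),
            t2.loc[present, "se"].to_numpy(), t2.loc[cds_ids, "se"].to_numpy(),
        )
        sig = bu["q"].to_numpy() < config.fdr
        up = sig & (bu["log2_beta_u"].to_numpy() > 0)
        down = sig & (bu["log2_beta_u"].to_numpy() < 0)
        gsig = gm["q"].to_numpy() < config.fdr
        n_inverse = int((up & gsig & (gm["log2_gamma"].to_numpy() < 0)).sum()
                        + (down & gsig & (gm["log2_gamma"].to_numpy() > 0)).sum())
        n_concord = int((up & gsig & (gm["log2_gamma"].to_numpy() > 0)).sum()
                        + (down & gsig & (gm["log2_gamma"].to_numpy() < 0)).sum())
        entry = {"sample1": s1, "sample2": s2, "n_uorfs": len(present),
                 "n_beta_u_significant": int(sig.sum()),
                 "n_inverse": n_inverse, "n_concordant": n_concord}
        if n_inverse + n_concord >= 1:
            chi2, p = te_stats.concordance_chi2(n_inverse, n_concord)
            entry.update({"concordance_chi2": chi2, "concordance_p": p})
        gamma_summary.append(entry)
    manifest["stages"]["gamma"] = gamma_summary

    # --- MK tests -------------------------------------------------------------
    table = popgen.MKTable.from_site_table(sites)
    alpha_ori = popgen.alpha_original(table, maf_threshold=config.maf)
    mk_entry = {"alpha_ori": alpha_ori,
                "alpha_true": sim.popgen.alpha_true,
                "d_ri": table.d_ri, "d_si": table.d_si}
    try:
        fit = popgen.asymptotic_mk(table)
        mk_entry.update({"alpha_asym": fit.alpha_asym, "fit_mode": fit.fit_mode})
    except ValueError as exc:
        manifest["warnings"].append(f"asymptotic MK skipped: {exc}")
    if config.mk_bootstrap_reps >= 100:
        med, lo, hi = popgen.bootstrap_alpha(
            table, lambda t: popgen.alpha_original(t, maf_threshold=config.maf),
            n_reps=config.mk_bootstrap_reps, seed=config.seed,
        )
        mk_entry["alpha_ori_ci"] = [med, lo, hi]
    manifest["stages"]["mk"] = mk_entry

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
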