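"""End-to-end orchestration: simulate -> quantify -> fit -> homology -> report.

Each stage reads and writes plain files (TIFF micrographs, CSV tables,
FASTA, Newick) so runs can be resumed, diffed and regenerated.  All
tables are written with a fixed float format and a fixed row order, so
two runs with the same configuration and seed produce byte-identical
CSVs.
"""

from __future__ import annotations

import logging
import os
import sys

import numpy as np
import pandas as pd

from . import io as sqio
from .align import conservation_classes, overall_homology, progressive_msa
from .assay import generate_assay
from .config import RunConfig
from .containers import MicrographMeta
from .phylo import DistanceMatrix, build_tree, clade_check
from .quant import (DoseResponse, classify_morphology, fit_half_max,
                    fit_sigmoid, rank_activity, sd_statistic,
                    summarize_timecourse)
from .seqsim import SequenceSimParams, simulate_sequence_family
from .sites import discriminative_site_scan

__all__ = ["run_simulate", "run_quantify", "run_homology", "run_report"]

log = logging.getLogger("seedquant")
_FMT = "%.10g"


def _csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FMT)


def run_simulate(cfg: RunConfig, outdir=None) -> pd.DataFrame:
    """Generate the full synthetic dataset on disk; returns the manifest."""
    outdir = outdir or cfg.outdir
    os.makedirs(outdir, exist_ok=True)
    kin = {sp: cfg.kinetic_params(sp, 0.0) for sp in cfg.species}
    img = {sp: cfg.imaging_params(sp) for sp in cfg.species}
    images = generate_assay(kin, img, cfg.aef_fractions, cfg.times_h,
                            cfg.replicates, cfg.seed_ceiling, cfg.seed)
    manifest = sqio.write_micrographs(images, os.path.join(outdir, "images"))

    fam = simulate_sequence_family(SequenceSimParams(rng_seed=cfg.seed))
    sqio.write_fasta(list(fam.records), os.path.join(outdir, "sequences.fasta"))
    with open(os.path.join(outdir, "true_tree.nwk"), "w") as fh:
        fh.write(fam.true_tree_newick + "\n")
    _csv(pd.DataFrame({"planted_column": list(fam.planted_columns)}),
         os.path.join(outdir, "true_sites.csv"))
    log.info("simulated %d micrographs and a %d-leaf sequence family",
             len(images), len(fam.records))
    return manifest


def run_quantify(cfg: RunConfig, manifest: pd.DataFrame, imagedir,
                 outdir=None) -> dict[str, pd.DataFrame]:
    """Quantify every manifest image; per-image failures are logged, not fatal."""
    outdir = outdir or cfg.outdir
    os.makedirs(outdir, exist_ok=True)
    rows, failures = [], []
    for rec in manifest.itertuples(index=False):
        path = os.path.join(imagedir, rec.path)
        try:
            meta = MicrographMeta(species=rec.species,
                                  aef_fraction=float(rec.aef_fraction),
                                  time_h=float(rec.time_h),
                                  replicate_id=int(rec.replicate))
            img = sqio.read_micrograph(path, meta)
            rows.append({**rec._asdict(), "sd": sd_statistic(img)})
        except Exception as exc:  # noqa: BLE001 - batch must survive bad files
            failures.append(rec.path)
            log.error("failed to quantify %s: %s", rec.path, exc)
    per_image = pd.DataFrame(rows).sort_values(
        ["species", "aef_fraction", "replicate", "time_h"],
        ignore_index=True)
    _csv(per_image, os.path.join(outdir, "per_image_sd.csv"))

    # time courses (mean +/- SEM over replicates)
    tc_rows = []
    for (sp, aef), grp in per_image.groupby(["species", "aef_fraction"]):
        piv = grp.pivot_table(index="time_h", columns="replicate", values="sd")
        for t, reps in piv.iterrows():
            vals = reps.dropna().to_numpy()
            sem = (float(np.std(vals, ddof=1) / np.sqrt(vals.size))
                   if vals.size > 1 else np.nan)
            tc_rows.append({"species": sp, "aef_fraction": aef, "time_h": t,
                            "sd_mean": float(vals.mean()), "sd_sem": sem,
                            "n": int(vals.size)})
    timecourse = pd.DataFrame(tc_rows).sort_values(
        ["species", "aef_fraction", "time_h"], ignore_index=True)
    _csv(timecourse, os.path.join(outdir, "timecourse.csv"))

    # endpoint dose-response + half-max fits per species
    t_end = per_image["time_h"].max()
    end = per_image[per_image["time_h"] == t_end]
    _csv(end.rename(columns={"sd": "endpoint_sd"}).drop(columns=["path"]),
         os.path.join(outdir, "doseresponse.csv"))
    fit_rows = []
    for sp, grp in end.groupby("species"):
        fracs = sorted(grp["aef_fraction"].unique())
        if len(fracs) >= 4:
            dr = DoseResponse(
                fractions=tuple(fracs),
                endpoint_sds=tuple(
                    tuple(grp[grp["aef_fraction"] == f]["sd"]) for f in fracs))
            hm = fit_half_max(dr)
            fit_rows.append({"species": sp, "fit": "half_max",
                             "bottom": hm.bottom, "top": hm.top,
                             "param": hm.half_max_fraction, "shape": hm.hill,
                             "rss": hm.rss, "flagged": hm.unidentifiable})
    for (sp, aef), grp in timecourse.groupby(["species", "aef_fraction"]):
        if aef != max(cfg.aef_fractions) or len(grp) < 5:
            continue
        from .quant import TimeCourse, TimeCoursePoint
        tc = TimeCourse(points=tuple(
            TimeCoursePoint(r.time_h, r.sd_mean, r.sd_sem, r.n)
            for r in grp.itertuples(index=False)))
        sf = fit_sigmoid(tc)
        fit_rows.append({"species": sp, "fit": "sigmoid",
                         "bottom": sf.baseline, "top": sf.plateau,
                         "param": sf.t50, "shape": sf.slope, "rss": sf.rss,
                         "flagged": sf.extrapolated})
    fits = pd.DataFrame(fit_rows).sort_values(["fit", "species"],
                                              ignore_index=True)
    _csv(fits, os.path.join(outdir, "fits.csv"))

    # morphology at endpoint, highest dose
    morph_rows = []
    top_dose = end[end["aef_fraction"] == end["aef_fraction"].max()]
    for rec in top_dose.itertuples(index=False):
        try:
            img = sqio.read_micrograph(os.path.join(imagedir, rec.path))
            rep = classify_morphology(img, cfg.morphology_cutoffs)
            morph_rows.append({"species": rec.species, "path": rec.path,
                               "label": rep.label,
                               "n_components": rep.n_components,
                               "largest_component_fraction":
                                   rep.largest_component_fraction,
                               "skeleton_length_per_area":
                                   rep.skeleton_length_per_area})
        except Exception as exc:  # noqa: BLE001
            failures.append(rec.path)
            log.error("failed to classify %s: %s", rec.path, exc)
    morphology = pd.DataFrame(morph_rows).sort_values(
        ["species", "path"], ignore_index=True)
    _csv(morphology, os.path.join(outdir, "morphology.csv"))

    # activity ranking at endpoint, highest dose
    ranking = rank_activity({
        sp: list(grp["sd"]) for sp, grp in top_dose.groupby("species")})
    rank_df = pd.DataFrame(
        [{"rank": i + 1, "species": sp, "mean_endpoint_sd": m, "tied": t}
         for i, (sp, m, t) in enumerate(ranking)])
    _csv(rank_df, os.path.join(outdir, "ranking.csv"))

    if failures:
        log.warning("%d image(s) failed quantification", len(failures))
    return {"per_image": per_image, "timecourse": timecourse, "fits": fits,
            "morphology": morphology, "ranking": rank_df,
            "failures": pd.DataFrame({"path": failures})}


def run_homology(cfg: RunConfig, records, outdir=None) -> dict:
    """MSA, homology summary, UPGMA tree and discriminative-site scan."""
    outdir = outdir or cfg.outdir
    os.makedirs(outdir, exist_ok=True)
    aln = progressive_msa(list(records), gap_open=cfg.gap_open,
                          gap_extend=cfg.gap_extend)
    sqio.write_alignment_fasta(aln, os.path.join(outdir, "alignment.fasta"))
    summary = overall_homology(aln)

    from .align import percent_identity
    n = len(aln.rows)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(aln.rows[i], aln.rows[j])
            dm[i, j] = dm[j, i] = 1.0 - (0.0 if np.isnan(pid) else pid) / 100.0
    tree = build_tree(DistanceMatrix(labels=aln.ids, matrix=dm))
    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(tree.to_newick() + "\n")

    classes = conservation_classes(aln)
    pd.DataFrame({"column": range(1, len(classes) + 1),
                  "class": classes}).to_csv(
        os.path.join(outdir, "conservation.tsv"), sep="\t", index=False)

    species = {r.id for r in records}
    groups = {g: tuple(m for m in members if m in species)
              for g, members in cfg_groups().items()}
    sites = []
    if all(groups.values()):
        reports = discriminative_site_scan(
            aln, set(groups["high"]), set(groups["low"]),
            strictness="disjoint")
        sites = [{"column": r.column,
                  "high_residues": "".join(r.group_a_residues),
                  "low_residues": "".join(r.group_b_residues),
                  "high_class": r.group_a_class or "mixed",
                  "low_class": r.group_b_class or "mixed"}
                 for r in reports]
    sites_df = pd.DataFrame(sites, columns=["column", "high_residues",
                                            "low_residues", "high_class",
                                            "low_class"])
    _csv(sites_df, os.path.join(outdir, "sites.csv"))
    _csv(pd.DataFrame([{
        "min_pairwise_identity": summary.min_pairwise_identity,
        "conserved_column_fraction": summary.conserved_column_fraction,
        "high_clade_monophyletic": clade_check(
            tree, set(groups["high"])) if groups["high"] else False,
    }]), os.path.join(outdir, "homology_summary.csv"))
    return {"alignment": aln, "summary": summary, "tree": tree,
            "sites": sites_df}


def cfg_groups() -> dict[str, tuple[str, ...]]:
    from .seqsim import DEFAULT_GROUPS
    return DEFAULT_GROUPS


def run_report(cfg: RunConfig, resultsdir, reportdir=None) -> str:
    """Collect tables into a self-contained report directory with plots.

    Missing inputs yield explicit "no data" entries rather than errors;
    regeneration is idempotent.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    reportdir = reportdir or os.path.join(resultsdir, "report")
    os.makedirs(reportdir, exist_ok=True)
    notes = []

    tc_path = os.path.join(resultsdir, "timecourse.csv")
    if os.path.exists(tc_path):
        tc = pd.read_csv(tc_path)
        _csv(tc, os.path.join(reportdir, "timecourse.csv"))
        fig, ax = plt.subplots(figsize=(6, 4))
        top = tc[tc["aef_fraction"] == tc["aef_fraction"].max()]
        for sp, grp in top.groupby("species"):
            ax.errorbar(grp["time_h"], grp["sd_mean"], yerr=grp["sd_sem"],
                        label=sp, marker="o", capsize=2)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("SD of pixel brightness")
        ax.legend(fontsize=8)
        fig.savefig(os.path.join(reportdir, "timecourse.png"), dpi=120)
        plt.close(fig)
    else:
        notes.append("timecourse: no data")

    dr_path = os.path.join(resultsdir, "doseresponse.csv")
    if os.path.exists(dr_path):
        dr = pd.read_csv(dr_path)
        _csv(dr, os.path.join(reportdir, "doseresponse.csv"))
        fig, ax = plt.subplots(figsize=(6, 4))
        for sp, grp in dr.groupby("species"):
            m = grp.groupby("aef_fraction")["endpoint_sd"].mean()
            ax.plot(m.index, m.values, marker="s", label=sp)
        ax.set_xlabel("AEF fraction")
        ax.set_ylabel("endpoint SD")
        ax.legend(fontsize=8)
        fig.savefig(os.path.join(reportdir, "doseresponse.png"), dpi=120)
        plt.close(fig)
    else:
        notes.append("doseresponse: no data")

    for name in ("ranking.csv", "fits.csv", "morphology.csv", "sites.csv",
                 "homology_summary.csv"):
        src = os.path.join(resultsdir, name)
        if os.path.exists(src):
            _csv(pd.read_csv(src), os.path.join(reportdir, name))
        else:
            notes.append(f"{name.removesuffix('.csv')}: no data")

    tree_src = os.path.join(resultsdir, "tree.nwk")
    if os.path.exists(tree_src):
        with open(tree_src) as fh:
            newick = fh.read()
        with open(os.path.join(reportdir, "tree.nwk"), "w") as fh:
            fh.write(newick)
    else:
        notes.append("tree: no data")

    with open(os.path.join(reportdir, "NOTES.txt"), "w") as fh:
        fh.write("\n".join(notes) + "\n" if notes else "all sections present\n")
    return reportdir
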