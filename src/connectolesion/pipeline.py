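"""End-to-end analysis: metrics, group tests, deviation tests, correlations.

Mirrors the study workflow: per-subject graph metrics on proportionally
thresholded, binarized connectomes; covariate-adjusted rank-based group
comparisons with BH-FDR per metric family; signed-rank deviation-from-zero
tests of control ΔGE; partial Spearman correlations of network measures
with regional pathology, neuropathologic staging and clinical variables.

All functions here are pure in-memory transforms on DataFrames and
connectome objects; file handling lives in :mod:`connectolesion.cli`.
The metric computation deliberately never sees group labels or pathology
(leakage firewall).
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .connectome import (
    ROI_NAMES,
    WeightedConnectome,
    binarize,
    default_roi_table,
    resolve_rois,
    threshold_proportional,
)
from .lesion import resilience_profile
from .metrics import eigenvector_centrality, global_efficiency, mean_clustering, nodal_clustering
from .stats import (
    StatError,
    bh_fdr,
    fisher_exact,
    group_difference_test,
    mad_outlier_flags,
    mann_whitney,
    one_sample_signed_rank,
    partial_spearman,
)

log = logging.getLogger(__name__)

#: (network measure, measure ROI, pathology ROIs) triples tested against the
#: five markers — the insula resilience statistic against pathology in the
#: insula and its connected regions, and parahippocampal centrality against
#: its own pathology.
DEFAULT_PATHOLOGY_TRIPLES = (
    ("dge", "dorsal_anterior_insula",
     ("dorsal_anterior_insula", "anterior_cingulate", "entorhinal")),
    ("ec", "parahippocampal", ("parahippocampal",)),
)

STAGING_COLUMNS = ("braak_asyn", "braak_nft", "thal")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis settings (defaults are the study conventions)."""

    threshold: float = 0.20
    threshold_of_nonzero: bool = False
    lesion_mode: str = "delete"
    fdr_joint: bool = False  # one family per metric (8 regions) by default
    outlier_n_mad: float = 3.0
    ec_max_norm: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        if self.lesion_mode not in ("delete", "zero"):
            raise ValueError("lesion_mode must be 'delete' or 'zero'")


# ---------------------------------------------------------------------------
# metrics


def compute_subject_metrics(
    conn: WeightedConnectome, config: AnalysisConfig, roi_table: dict | None = None
) -> dict[str, float]:
    """All network measures for one subject (global + 8 per-ROI x 3)."""
    thr = threshold_proportional(conn, config.threshold, config.threshold_of_nonzero)
    g = binarize(thr)
    rois = resolve_rois(g.labels, roi_table)
    ec = eigenvector_centrality(g)
    if config.ec_max_norm:
        ec = ec / ec.max()
    cc = nodal_clustering(g)
    out: dict[str, float] = {
        "ge": global_efficiency(g),
        "mean_cc": mean_clustering(g),
    }
    for roi in rois.roi_names:
        i = rois.node_indices[roi]
        out[f"ec_{roi}"] = float(ec[i])
        out[f"cc_{roi}"] = float(cc[i])
    dge = resilience_profile(g, rois, mode=config.lesion_mode)
    for roi, v in dge.items():
        out[f"dge_{roi}"] = v
    return out


def run_metrics(
    connectomes: Mapping[str, WeightedConnectome],
    config: AnalysisConfig | None = None,
    roi_table: dict | None = None,
) -> pd.DataFrame:
    """Per-subject MetricsTable (wide): subject_id + 26 metric columns."""
    config = config or AnalysisConfig()
    rows = []
    for sid in connectomes:
        try:
            rows.append({"subject_id": sid, **compute_subject_metrics(connectomes[sid], config, roi_table)})
        except Exception as exc:
            raise RuntimeError(f"metric computation failed for subject {sid!r}: {exc}") from exc
    return pd.DataFrame(rows)


def metrics_long(metrics: pd.DataFrame) -> pd.DataFrame:
    """Tidy long form (subject_id, metric, region, value) of the wide table."""
    rows = []
    for _, r in metrics.iterrows():
        for col in metrics.columns:
            if col == "subject_id":
                continue
            if "_" in col and col.split("_", 1)[1] in ROI_NAMES:
                metric, region = col.split("_", 1)
            else:
                metric, region = col, "global"
            rows.append(dict(subject_id=r["subject_id"], metric=metric, region=region, value=r[col]))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# joins and covariates


def _check_join(metrics: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    orphans = set(metrics["subject_id"]) - set(subjects["subject_id"])
    if orphans:
        raise KeyError(f"subjects missing from subject table: {sorted(orphans)}")
    merged = metrics.merge(subjects, on="subject_id", how="left", validate="1:1")
    return merged


def _covariates(df: pd.DataFrame, cols=("age_at_death", "sex", "postmortem_delay")) -> np.ndarray:
    out = []
    for c in cols:
        v = df[c]
        if c == "sex":
            v = (v == "M").astype(float)
        out.append(np.asarray(v, float))
    return np.column_stack(out)


# ---------------------------------------------------------------------------
# group comparisons


def run_group_comparisons(
    metrics: pd.DataFrame, subjects: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Rank-based PD-vs-control tests, FDR-corrected per metric family.

    Families: 8 regional tests each for eigenvector centrality, clustering
    coefficient and ΔGE (or one joint family of 24 with ``fdr_joint``),
    plus the two global measures.  Every test is also rerun excluding
    subjects flagged by the robust MAD rule; both rows are reported.
    """
    config = config or AnalysisConfig()
    df = _check_join(metrics, subjects)
    is_pd = (df["group"] == "PD").to_numpy()
    cov = _covariates(df)
    specs = [("global", "ge", "ge"), ("global", "mean_cc", "mean_cc")]
    for fam, prefix in (("ec", "ec"), ("cc", "cc"), ("dge", "dge")):
        for roi in ROI_NAMES:
            specs.append((fam, prefix, f"{prefix}_{roi}"))

    rows = []
    for exclude_outliers in (False, True):
        for family, metric, col in specs:
            region = col.split("_", 1)[1] if col not in ("ge", "mean_cc") else "global"
            values = df[col].to_numpy(float)
            mask = np.ones(len(df), bool)
            n_flagged = 0
            if exclude_outliers:
                flags = np.zeros(len(df), bool)
                for grp_mask in (is_pd, ~is_pd):
                    flags[grp_mask] = mad_outlier_flags(values[grp_mask], config.outlier_n_mad)
                mask = ~flags
                n_flagged = int(flags.sum())
            try:
                res = group_difference_test(
                    values[mask], is_pd[mask], cov[mask], region=region, metric=metric
                )
                rows.append(dict(
                    family=family, metric=metric, region=region,
                    estimate=res.group_coefficient, d=res.cohen_d, p=res.p,
                    p_fdr=np.nan, n_control=res.n_control, n_pd=res.n_pd,
                    outliers_excluded=exclude_outliers, n_outliers=n_flagged, error="",
                ))
            except StatError as exc:
                log.warning("group test %s/%s failed: %s", metric, region, exc)
                rows.append(dict(
                    family=family, metric=metric, region=region,
                    estimate=np.nan, d=np.nan, p=np.nan, p_fdr=np.nan,
                    n_control=0, n_pd=0, outliers_excluded=exclude_outliers,
                    n_outliers=n_flagged, error=str(exc),
                ))
    out = pd.DataFrame(rows)
    for excl in (False, True):
        sub = out["outliers_excluded"] == excl
        families = (
            {"global": ["global"], "regional": ["ec", "cc", "dge"]}
            if config.fdr_joint
            else {f: [f] for f in ("global", "ec", "cc", "dge")}
        )
        for fams in families.values():
            sel = sub & out["family"].isin(fams) & out["p"].notna()
            if sel.any():
                out.loc[sel, "p_fdr"] = bh_fdr(out.loc[sel, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# deviation-from-zero tests


def run_deviation_tests(
    metrics: pd.DataFrame, subjects: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Signed-rank test of control ΔGE against zero, per ROI, FDR over 8."""
    df = _check_join(metrics, subjects)
    ctrl = df[df["group"] == "control"]
    if len(ctrl) < 5:
        raise StatError(f"need >= 5 controls for deviation tests, have {len(ctrl)}")
    rows = []
    for roi in ROI_NAMES:
        vals = ctrl[f"dge_{roi}"].to_numpy(float)
        try:
            p = one_sample_signed_rank(vals)
            err = ""
        except StatError as exc:
            p, err = np.nan, str(exc)
        rows.append(dict(region=roi, median_dge=float(np.median(vals)), p=p, p_fdr=np.nan, error=err))
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "p_fdr"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# correlations


def _partial_corr_row(df, xcol_values, ycol_values, cov_cols, scope, **meta):
    ok = np.isfinite(xcol_values) & np.isfinite(ycol_values) & np.isfinite(cov_cols).all(axis=1)
    try:
        r, p = partial_spearman(xcol_values[ok], ycol_values[ok], cov_cols[ok])
        return dict(scope=scope, r_s=r, p=p, p_fdr=np.nan, n=int(ok.sum()), error="", **meta)
    except StatError as exc:
        return dict(scope=scope, r_s=np.nan, p=np.nan, p_fdr=np.nan, n=int(ok.sum()),
                    error=str(exc), **meta)


def run_pathology_correlations(
    metrics: pd.DataFrame,
    pathology: pd.DataFrame,
    subjects: pd.DataFrame,
    config: AnalysisConfig | None = None,
    triples=DEFAULT_PATHOLOGY_TRIPLES,
) -> pd.DataFrame:
    """Partial Spearman of network measures vs the 5 regional markers.

    Each (measure, measure-ROI, pathology-ROI) triple is tested within the
    PD group and across the whole cohort, with age/sex/postmortem-delay
    covariates; FDR is applied across the 5 markers of each family.
    """
    from .cohort import PATHOLOGY_MARKERS

    df = _check_join(metrics, subjects)
    missing_rois = set().union(*(t[2] for t in triples)) - set(pathology["roi"])
    if missing_rois:
        raise KeyError(f"pathology table lacks ROIs: {sorted(missing_rois)}")
    rows = []
    for measure, measure_roi, path_rois in triples:
        col = f"{measure}_{measure_roi}"
        for path_roi in path_rois:
            wide = pathology[pathology["roi"] == path_roi].set_index("subject_id")
            joined = df.join(wide[list(PATHOLOGY_MARKERS)], on="subject_id")
            for scope in ("PD", "all"):
                sub = joined if scope == "all" else joined[joined["group"] == "PD"]
                cov = _covariates(sub)
                y = sub[col].to_numpy(float)
                for marker in PATHOLOGY_MARKERS:
                    rows.append(_partial_corr_row(
                        sub, sub[marker].to_numpy(float), y, cov, scope,
                        measure=measure, measure_roi=measure_roi,
                        pathology_roi=path_roi, marker=marker,
                    ))
    out = pd.DataFrame(rows)
    for (_, _, _, scope), grp in out.groupby(["measure", "measure_roi", "pathology_roi", "scope"]):
        ok = grp["p"].notna()
        if ok.any():
            out.loc[grp.index[ok], "p_fdr"] = bh_fdr(grp.loc[ok, "p"].to_numpy())
    return out


def run_staging_correlations(
    metrics: pd.DataFrame, subjects: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Insula-ΔGE correlations with staging (combined cohort) and clinical data.

    Staging systems (Braak α-synuclein, Braak NFT, Thal) are treated as
    numeric ordinals and FDR-corrected as a family of 3.  Demographic and
    clinical correlations use postmortem delay as the only covariate and
    are FDR-corrected per scope.
    """
    df = _check_join(metrics, subjects)
    y_all = df["dge_dorsal_anterior_insula"].to_numpy(float)
    cov3 = _covariates(df)
    rows = []
    for stage in STAGING_COLUMNS:
        rows.append(_partial_corr_row(
            df, df[stage].to_numpy(float), y_all, cov3, "all",
            variable=stage, family="staging",
        ))
    pmd = _covariates(df, cols=("postmortem_delay",))
    clinical_all = {"sex": (df["sex"] == "M").to_numpy(float), "age_at_death": df["age_at_death"].to_numpy(float)}
    for name, x in clinical_all.items():
        rows.append(_partial_corr_row(df, x, y_all, pmd, "all", variable=name, family="clinical"))
    pd_df = df[df["group"] == "PD"]
    y_pd = pd_df["dge_dorsal_anterior_insula"].to_numpy(float)
    pmd_pd = _covariates(pd_df, cols=("postmortem_delay",))
    clinical_pd = {
        "sex": (pd_df["sex"] == "M").to_numpy(float),
        "age_at_death": pd_df["age_at_death"].to_numpy(float),
        "disease_duration": pd_df["disease_duration"].to_numpy(float),
        "cdr": pd_df["cdr"].to_numpy(float),
    }
    for name, x in clinical_pd.items():
        rows.append(_partial_corr_row(pd_df, x, y_pd, pmd_pd, "PD", variable=name, family="clinical"))
    out = pd.DataFrame(rows)
    for (_, scope), grp in out.groupby(["family", "scope"]):
        ok = grp["p"].notna()
        if ok.any():
            out.loc[grp.index[ok], "p_fdr"] = bh_fdr(grp.loc[ok, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# demographics and report


def demographics_table(subjects: pd.DataFrame) -> dict:
    """Group comparison of demographics: Mann-Whitney (continuous), Fisher (sex)."""
    ctrl = subjects[subjects["group"] == "control"]
    pdg = subjects[subjects["group"] == "PD"]
    sex_table = np.array([
        [(ctrl["sex"] == "M").sum(), (ctrl["sex"] == "F").sum()],
        [(pdg["sex"] == "M").sum(), (pdg["sex"] == "F").sum()],
    ])
    return {
        "n_control": int(len(ctrl)),
        "n_pd": int(len(pdg)),
        "age_control_mean": float(ctrl["age_at_death"].mean()),
        "age_pd_mean": float(pdg["age_at_death"].mean()),
        "age_p": mann_whitney(ctrl["age_at_death"], pdg["age_at_death"]),
        "pmd_p": mann_whitney(ctrl["postmortem_delay"], pdg["postmortem_delay"]),
        "sex_p": fisher_exact(sex_table),
    }


def run_analysis(
    metrics: pd.DataFrame,
    subjects: pd.DataFrame,
    pathology: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> dict:
    """All statistical stages on precomputed metrics; JSON-serializable dict."""
    config = config or AnalysisConfig()
    results = {
        "config": dataclasses.asdict(config),
        "demographics": demographics_table(subjects),
        "group_tests": run_group_comparisons(metrics, subjects, config).to_dict("records"),
        "deviation_tests": run_deviation_tests(metrics, subjects, config).to_dict("records"),
        "pathology_correlations": run_pathology_correlations(
            metrics, pathology, subjects, config
        ).to_dict("records"),
        "staging_correlations": run_staging_correlations(metrics, subjects, config).to_dict("records"),
    }
    return _jsonify(results)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def render_report(results: dict) -> str:
    """Human-readable Markdown generated from results.json content alone."""
    lines = ["# Structural network analysis report", ""]
    demo = results["demographics"]
    lines += [
        "## Demographics",
        "",
        f"- Controls: n={demo['n_control']}, mean age {demo['age_control_mean']:.1f} y",
        f"- PD: n={demo['n_pd']}, mean age {demo['age_pd_mean']:.1f} y",
        f"- Age Mann-Whitney p = {demo['age_p']:.3g}; "
        f"PMD p = {demo['pmd_p']:.3g}; sex Fisher p = {demo['sex_p']:.3g}",
        "",
        "## Group comparisons (rank-based, age/sex/PMD adjusted)",
        "",
        "| metric | region | estimate | d | p | p_FDR | outliers excluded |",
        "|---|---|---|---|---|---|---|",
    ]
    for r in results["group_tests"]:
        lines.append(
            f"| {r['metric']} | {r['region']} | {_fmt(r['estimate'])} | {_fmt(r['d'])} "
            f"| {_fmt(r['p'])} | {_fmt(r['p_fdr'])} | {r['outliers_excluded']} |"
        )
    lines += ["", "## Control ΔGE deviation from zero", "",
              "| region | median ΔGE | p | p_FDR |", "|---|---|---|---|"]
    for r in results["deviation_tests"]:
        lines.append(f"| {r['region']} | {_fmt(r['median_dge'])} | {_fmt(r['p'])} | {_fmt(r['p_fdr'])} |")
    lines += ["", "## Pathology correlations (partial Spearman)", "",
              "| measure | measure ROI | pathology ROI | marker | scope | r_s | p | p_FDR | n |",
              "|---|---|---|---|---|---|---|---|---|"]
    for r in results["pathology_correlations"]:
        lines.append(
            f"| {r['measure']} | {r['measure_roi']} | {r['pathology_roi']} | {r['marker']} "
            f"| {r['scope']} | {_fmt(r['r_s'])} | {_fmt(r['p'])} | {_fmt(r['p_fdr'])} | {r['n']} |"
        )
    lines += ["", "## Staging and clinical correlations", "",
              "| family | variable | scope | r_s | p | p_FDR | n |", "|---|---|---|---|---|---|---|"]
    for r in results["staging_correlations"]:
        lines.append(
            f"| {r['family']} | {r['variable']} | {r['scope']} | {_fmt(r['r_s'])} "
            f"| {_fmt(r['p'])} | {_fmt(r['p_fdr'])} | {r['n']} |"
        )
    cfg = results["config"]
    lines += ["", "## Configuration", ""]
    for k in sorted(cfg):
        lines.append(f"- {k}: {cfg[k]}")
    lines.append("")
    return "\n".join(lines)


def _fmt(v) -> str:
    if v is None:
        return "—"
    return f"{v:.4g}"


def write_report(results: dict, out_dir: str | Path) -> None:
    """Write results.json (deterministic) and the Markdown report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "results.json", "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")
    (out / "report.md").write_text(render_report(results), encoding="utf-8")
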