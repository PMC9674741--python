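"""Repeated-measures statistics and figure-equivalent summary outputs.

Semantic type is a within-subject factor (concrete and abstract models of
one subject share their initial wiring), so all tests are repeated-
measures: multi-way within-subject ANOVAs (uncorrected degrees of
freedom) and Bonferroni-corrected paired t-tests with a base critical p
of 0.01.  Summary tables (means and across-subject 95% CIs) are the
contract; rendered plots are best-effort companions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.anova import AnovaRM

from semground.architecture import area, areas_by
from semground import assembly

BASE_ALPHA = 0.01


@dataclass
class TestReport:
    effect: str
    statistic: float      # F or t
    df: tuple
    p: float
    critical_p: float
    significant: bool
    means: dict | None = None


def add_area_factors(frame: pd.DataFrame) -> pd.DataFrame:
    """Attach the topographical factor columns derived from the area."""
    frame = frame.copy()
    frame["peri_extra"] = [
        "peri" if area(a).system == "peri-sylvian" else "extra"
        for a in frame["area"]]
    frame["temp_front"] = [area(a).lobe for a in frame["area"]]
    frame["centrality"] = [area(a).centrality for a in frame["area"]]
    return frame


def rm_anova(frame: pd.DataFrame, dv: str, within: list[str],
             subject: str = "subject_id") -> pd.DataFrame:
    """Within-subject ANOVA; one value per subject x factor cell.

    The frame is aggregated (mean) to one observation per cell first.
    Returns the ANOVA table with F, uncorrected dfs and p per effect.
    """
    cells = frame.groupby([subject] + within)[dv].mean().reset_index()
    counts = cells.groupby(within).size()
    if counts.nunique() > 1:
        raise ValueError("unbalanced design: unequal cell counts")
    res = AnovaRM(cells, depvar=dv, subject=subject, within=within).fit()
    table = res.anova_table.copy()
    table.index.name = "effect"
    return table.reset_index()


def bonferroni_paired_tests(
        comparisons: list[tuple[str, np.ndarray, np.ndarray]],
        base_alpha: float = BASE_ALPHA) -> list[TestReport]:
    """Paired t-tests with a Bonferroni-corrected critical p.

    ``comparisons`` is a list of (label, values_a, values_b) with values
    paired by subject.  critical p = base_alpha / number of comparisons.
    """
    if not comparisons:
        raise ValueError("no comparisons given")
    critical = base_alpha / len(comparisons)
    reports = []
    for label, a, b in comparisons:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"{label}: unpaired values")
        t, p = scipy.stats.ttest_rel(a, b)
        reports.append(TestReport(
            effect=label, statistic=float(t), df=(a.size - 1,),
            p=float(p), critical_p=critical, significant=bool(p < critical),
            means={"a": float(a.mean()), "b": float(b.mean())}))
    return reports


def _ci95(x) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    return float(scipy.stats.t.ppf(0.975, x.size - 1)
                 * x.std(ddof=1) / np.sqrt(x.size))


def _agg_subject_then_grand(frame: pd.DataFrame, value: str,
                            by: list[str]) -> pd.DataFrame:
    per_subject = frame.groupby(by + ["subject_id"])[value].mean().reset_index()
    return (per_subject.groupby(by)[value]
            .agg(mean="mean", ci95=_ci95).reset_index())


def standard_anova_battery(size_frame: pd.DataFrame,
                           shared_table: pd.DataFrame,
                           proportions: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """The study's ANOVA battery on CA sizes, sharedness and proportions.

    Returns the 4-way CA-size ANOVA, the extra- and peri-sylvian 3-way
    follow-ups (peri-sylvian with primary areas excluded, leaving 2
    centrality levels), the 2x2x2 sharedness analysis on unique vs shared
    counts in primary/central extra-sylvian areas and the 2-way analysis
    of the proportion of shared neurons.
    """
    sizes = add_area_factors(size_frame)
    out: dict[str, pd.DataFrame] = {}
    out["ca_size_4way"] = rm_anova(
        sizes, "size",
        ["semantic_type", "peri_extra", "temp_front", "centrality"])
    extra = sizes[sizes["peri_extra"] == "extra"]
    out["ca_size_extra_3way"] = rm_anova(
        extra, "size", ["semantic_type", "temp_front", "centrality"])
    peri = sizes[(sizes["peri_extra"] == "peri")
                 & (sizes["centrality"] != "primary")]
    out["ca_size_peri_3way"] = rm_anova(
        peri, "size", ["semantic_type", "temp_front", "centrality"])

    sh = add_area_factors(shared_table)
    sh = sh[(sh["peri_extra"] == "extra")
            & (sh["centrality"].isin(["primary", "central"]))].copy()
    sh["shared"] = np.where(sh["sharedness"] >= 2, "shared", "unique")
    counts = (sh.groupby(["subject_id", "semantic_type", "centrality",
                          "shared", "concept_id"])["count"].sum()
              .reset_index())
    out["sharedness_2x2x2"] = rm_anova(
        counts, "count", ["semantic_type", "centrality", "shared"])

    props = add_area_factors(proportions)
    out["proportion_2way"] = rm_anova(
        props, "proportion", ["semantic_type", "centrality"])
    return out


def report_figures(result, out_dir: str | Path, *,
                   control_result=None, plots: bool = True) -> dict[str, pd.DataFrame]:
    """Figure-equivalent summary tables (and plots) from an experiment.

    Writes fig4.csv (instance-CA sizes per area), fig5.csv (neuron counts
    by sharedness level), fig6a/b/c.csv (unique/shared counts per area,
    their primary-vs-central collapse, and the percent change of shared
    counts), fig7.csv (proportion shared across extra-sylvian areas) and,
    if a halved-training control condition is present, fig8.csv.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cas = assembly.cas_from_result(result)
    main_cas = {(sid, cond): v for (sid, cond), v in cas.items()
                if cond in ("concrete", "abstract")}
    sizes = assembly.ca_size_frame(main_cas)
    table = assembly.sharedness_table(main_cas)
    tables: dict[str, pd.DataFrame] = {}

    tables["fig4"] = assembly.instance_ca_sizes(sizes, "area")

    counts = (table.groupby(["subject_id", "semantic_type", "area",
                             "sharedness", "concept_id"])["count"].sum()
              .reset_index())
    tables["fig5"] = _agg_subject_then_grand(
        counts, "count", ["semantic_type", "area", "sharedness"])

    extra = areas_by(system="extra-sylvian")
    t6 = table[table["area"].isin(extra)].copy()
    t6["shared"] = np.where(t6["sharedness"] >= 2, "shared", "unique")
    c6 = (t6.groupby(["subject_id", "semantic_type", "area", "shared",
                      "concept_id"])["count"].sum().reset_index())
    tables["fig6a"] = _agg_subject_then_grand(
        c6, "count", ["semantic_type", "area", "shared"])
    t6b = add_area_factors(t6)
    t6b = t6b[t6b["centrality"].isin(["primary", "central"])]
    c6b = (t6b.groupby(["subject_id", "semantic_type", "centrality",
                        "shared", "concept_id"])["count"].sum().reset_index())
    tables["fig6b"] = _agg_subject_then_grand(
        c6b, "count", ["semantic_type", "centrality", "shared"])
    pct = assembly.percent_change_shared(table)
    tables["fig6c"] = (pct.groupby("semantic_type")["percent_change"]
                       .agg(mean="mean", ci95=_ci95).reset_index())

    props = assembly.proportion_shared(table)
    tables["fig7"] = _agg_subject_then_grand(
        props, "proportion", ["semantic_type", "area"])

    if "concrete_control" in result.conditions:
        ctrl_cas = {(sid, "concrete_control"): v
                    for (sid, cond), v in cas.items()
                    if cond == "concrete_control"}
        ctrl_table = assembly.sharedness_table(ctrl_cas)
        ctrl_props = assembly.proportion_shared(ctrl_table)
        both = pd.concat([
            props.assign(condition=props["semantic_type"]),
            ctrl_props.assign(condition="concrete_control")],
            ignore_index=True)
        tables["fig8"] = _agg_subject_then_grand(
            both, "proportion", ["condition", "area"])

    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    if plots:
        _render_plots(tables, out)
    return tables


def _render_plots(tables: dict[str, pd.DataFrame], out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name, df in tables.items():
        fig, ax = plt.subplots(figsize=(7, 4))
        value_col = [c for c in ("mean", "percent_change") if c in df][0]
        cat_cols = [c for c in df.columns
                    if c not in (value_col, "ci95", "n_subjects")]
        labels = df[cat_cols].astype(str).agg("|".join, axis=1)
        err = df["ci95"] if "ci95" in df else None
        ax.bar(range(len(df)), df[value_col], yerr=err)
        ax.set_xticks(range(len(df)))
        ax.set_xticklabels(labels, rotation=90, fontsize=5)
        ax.set_ylabel(value_col)
        ax.set_title(name)
        fig.tight_layout()
        fig.savefig(out / f"{name}.png", dpi=120)
        plt.close(fig)
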