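"""End-to-end orchestration: simulate -> score -> analyze -> report.

A run produces a bundle directory containing the scores TSV, a
machine-readable analysis JSON, a human-readable text report laid out like a
cohort-characteristics table, the run log, and the serialized configuration.
Every run is fully reproducible from its seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import association_stats as ast
from . import io as pio
from .prs_engine import results_to_frame, score_cohort
from .synthetic_cohort import CohortConfig, simulate_cohort
from .variant_model import load_builtin_panel

logger = logging.getLogger(__name__)

DEFAULT_CANDIDATES = ["prs", "smoking", "sex", "age", "hypertension", "statin"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    With ``genotypes``/``phenotypes`` unset, a synthetic cohort is simulated
    from ``cohort`` (or defaults) under ``seed``.
    """

    out_dir: str | Path = "prs_ldl_run"
    genotypes: Optional[str] = None
    genotype_format: Optional[str] = None
    phenotypes: Optional[str] = None
    panel_name: str = "futema2015_modified"
    weight_file: Optional[str] = None
    apoe_policy: str = "default"
    ldl_threshold: float = 4.9
    selection_alpha: float = 0.05
    candidates: list[str] = field(default_factory=lambda: list(DEFAULT_CANDIDATES))
    #: fit the LDL-C>threshold model within the comparison group only
    ldl_model_within_comparison: bool = True
    seed: int = 7
    cohort: Optional[CohortConfig] = None
    log_level: str = "INFO"


def _load_panel(config: RunConfig):
    panel = load_builtin_panel(config.panel_name)
    if config.weight_file:
        panel = pio.read_weight_file(config.weight_file, template=panel)
    return panel


def _design_matrix(df: pd.DataFrame, candidates: list[str]) -> pd.DataFrame:
    design = pd.DataFrame(index=df.index)
    for term in candidates:
        if term == "sex":
            design["sex"] = (df["sex"] == "M").astype(float)
        else:
            design[term] = pd.to_numeric(df[term], errors="coerce")
    return design


def _fit_to_dict(fit: ast.LogisticFitResult) -> dict:
    return {
        "outcome": fit.outcome,
        "n": fit.n,
        "log_likelihood": fit.log_likelihood,
        "terms": [
            {
                "term": t.term,
                "beta": t.beta,
                "se": t.se,
                "odds_ratio": t.odds_ratio,
                "ci95": [t.ci_low, t.ci_high],
                "p_value": t.p_value,
            }
            for t in fit.terms
        ],
    }


def _trace_to_dict(trace: ast.SelectionTrace) -> dict:
    return {
        "steps": [
            {"dropped": s.dropped, "p_value": s.p_value, "surviving": list(s.surviving)}
            for s in trace.steps
        ],
        "final_terms": list(trace.final_terms),
    }


def analyze_cohort(
    scores: pd.DataFrame,
    phenotypes: pd.DataFrame,
    ldl_threshold: float = 4.9,
    selection_alpha: float = 0.05,
    candidates: Optional[list[str]] = None,
    ldl_model_within_comparison: bool = True,
) -> dict:
    """Run the full statistics stage on joined score + phenotype tables.

    Returns a JSON-serialisable block: group characteristics with rank and
    contingency tests, the PRS group comparison, the case-status logistic
    model (backward-selected), and the LDL-C > threshold model.
    """
    candidates = candidates or list(DEFAULT_CANDIDATES)
    df = phenotypes.merge(scores[["sample_id", "prs"]], on="sample_id", validate="1:1")
    df = df[df["prs"].notna()].reset_index(drop=True)
    groups = {label: sub for label, sub in df.groupby("group")}
    if set(groups) != {"patient", "comparison"}:
        raise ValueError(f"expected groups patient/comparison, got {sorted(groups)}")

    block: dict = {"n": {g: int(len(sub)) for g, sub in groups.items()}}

    # Quantitative variables: tie-corrected rank test.
    for var in ("prs", "ldl_c", "age"):
        test = ast.kruskal_wallis({g: sub[var].to_numpy(float) for g, sub in groups.items()})
        block[var] = {
            "kruskal_H": test.statistic,
            "df": test.df,
            "p_value": test.p_value,
            "groups": {
                s.label: {"n": s.n, "median": s.median, "min": s.minimum, "max": s.maximum}
                for s in test.groups
            },
        }

    # Categorical variables: chi-square (2x2, no continuity correction) and
    # Fisher's exact test.
    categorical = {
        "sex": df["sex"] == "M",
        "smoking": df["smoking"] == 1,
        "hypertension": df["hypertension"] == 1,
        "statin": df["statin"] == 1,
    }
    block["categorical"] = {}
    for var, indicator in categorical.items():
        table = np.array(
            [
                [int(indicator[df["group"] == g].sum()), int((~indicator)[df["group"] == g].sum())]
                for g in ("patient", "comparison")
            ]
        )
        entry: dict = {
            "counts": {
                g: {"yes": int(table[i, 0]), "no": int(table[i, 1]),
                    "pct": round(100 * table[i, 0] / table[i].sum(), 1)}
                for i, g in enumerate(("patient", "comparison"))
            }
        }
        try:
            chi2 = ast.pearson_chi2(table)
            entry["chi2"] = chi2.statistic
            entry["chi2_p"] = chi2.p_value
            entry["fisher_p"] = ast.fisher_exact(table)
        except ast.StatError:
            pass  # degenerate margin: counts are still reported
        block["categorical"][var] = entry

    # Case-status model: outcome = patient group, backward-selected.
    y_case = (df["group"] == "patient").astype(int).to_numpy()
    design = _design_matrix(df, candidates)
    trace, fit = ast.backward_select(
        y_case, design, alpha=selection_alpha, outcome_name="case_status"
    )
    block["case_model"] = {"selection": _trace_to_dict(trace), "fit": _fit_to_dict(fit)}

    # LDL-C > threshold model (within the comparison group by default).
    ldl_df = groups["comparison"] if ldl_model_within_comparison else df
    ldl_df = ldl_df.reset_index(drop=True)
    y_ldl = ast.dichotomize_ldl(ldl_df["ldl_c"], threshold=ldl_threshold)
    ldl_block: dict = {
        "threshold": ldl_threshold,
        "n_above": int(y_ldl.sum()),
        "n": int(y_ldl.notna().sum()),
        "within_comparison_group": ldl_model_within_comparison,
    }
    ldl_candidates = [c for c in candidates if c != "statin" or ldl_df["statin"].nunique() > 1]
    mask = y_ldl.notna()
    try:
        ldl_trace, ldl_fit = ast.backward_select(
            y_ldl[mask].astype(int).to_numpy(),
            _design_matrix(ldl_df[mask], ldl_candidates),
            alpha=selection_alpha,
            outcome_name=f"ldl_gt_{ldl_threshold}",
        )
        ldl_block["selection"] = _trace_to_dict(ldl_trace)
        ldl_block["fit"] = _fit_to_dict(ldl_fit)
    except (ast.StatError, ast.SeparationError, ast.ConvergenceError) as exc:
        ldl_block["error"] = str(exc)
    block["ldl_model"] = ldl_block

    # PRS distribution summary (histogram counts per group).
    edges = np.round(np.arange(-0.9, 1.35, 0.1), 10)
    block["prs_distribution"] = {
        "bin_edges": edges.tolist(),
        "counts": {
            g: np.histogram(sub["prs"].to_numpy(float), bins=edges)[0].tolist()
            for g, sub in groups.items()
        },
    }
    return block


def render_report(analysis: dict) -> str:
    """Human-readable report mirroring a two-group characteristics table."""
    lines = ["LDL-C SNP score analysis", "=" * 60, ""]
    n = analysis["n"]
    lines.append(f"Patient group n={n['patient']}, comparison group n={n['comparison']}")
    lines.append("")
    lines.append(f"{'Variable':<22}{'Patient':>16}{'Comparison':>16}{'p':>8}")
    lines.append("-" * 62)
    for var, label in (("age", "Age (years)"), ("ldl_c", "LDL-C (mmol/L)"), ("prs", "PRS")):
        g = analysis[var]["groups"]
        p, c = g["patient"], g["comparison"]
        lines.append(
            f"{label:<22}"
            f"{p['median']:>7.3g} ({p['min']:.3g}-{p['max']:.3g})"
            f"{c['median']:>8.3g} ({c['min']:.3g}-{c['max']:.3g})"
            f"{analysis[var]['p_value']:>8.3f}"
        )
    for var, entry in analysis["categorical"].items():
        p, c = entry["counts"]["patient"], entry["counts"]["comparison"]
        stat = f"chi2={entry['chi2']:.3f}" if "chi2" in entry else ""
        lines.append(
            f"{var:<22}{p['yes']:>7d} ({p['pct']:.1f}%)"
            f"{c['yes']:>8d} ({c['pct']:.1f}%)"
            f"{entry.get('chi2_p', entry.get('fisher_p', float('nan'))):>8.3f}  {stat}"
        )
    lines.append("")
    lines.append("Case-status logistic model (backward-selected):")
    for t in analysis["case_model"]["fit"]["terms"]:
        if t["term"] == "intercept":
            continue
        lines.append(
            f"  {t['term']:<14} OR {t['odds_ratio']:.3f} "
            f"(95% CI {t['ci95'][0]:.3f}-{t['ci95'][1]:.3f}), p={t['p_value']:.3f}"
        )
    ldl = analysis["ldl_model"]
    lines.append("")
    lines.append(
        f"LDL-C > {ldl['threshold']} mmol/L model "
        f"({'comparison group' if ldl['within_comparison_group'] else 'all samples'}, "
        f"{ldl['n_above']}/{ldl['n']} above threshold):"
    )
    if "fit" in ldl:
        terms = [t for t in ldl["fit"]["terms"] if t["term"] != "intercept"]
        if not terms:
            lines.append("  no term retained at the selection threshold")
        for t in terms:
            lines.append(
                f"  {t['term']:<14} OR {t['odds_ratio']:.3f} "
                f"(95% CI {t['ci95'][0]:.3f}-{t['ci95'][1]:.3f}), p={t['p_value']:.3f}"
            )
    else:
        lines.append(f"  model not fit: {ldl['error']}")
    return "\n".join(lines) + "\n"


def plot_prs_distribution(analysis: dict, path: str | Path) -> None:
    """Grouped histogram of the PRS distribution (counts of individuals)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dist = analysis["prs_distribution"]
    edges = np.asarray(dist["bin_edges"])
    centers = (edges[:-1] + edges[1:]) / 2
    width = (edges[1] - edges[0]) * 0.42
    fig, axis = plt.subplots(figsize=(7, 4))
    axis.bar(centers - width / 2, dist["counts"]["patient"], width=width, label="patient")
    axis.bar(centers + width / 2, dist["counts"]["comparison"], width=width, label="comparison")
    axis.set_xlabel("LDL-C SNP score")
    axis.set_ylabel("individuals")
    axis.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate (or load) -> score -> analyze and write the bundle.

    Returns a dict of written paths plus the analysis block.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("prs_ldl")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    try:
        panel = _load_panel(config)
        logger.info(
            "panel %s v%s, seed %d, APOE policy %s",
            panel.name, panel.version, config.seed, config.apoe_policy,
        )
        if config.genotypes:
            samples = pio.read_genotypes(config.genotypes, panel, config.genotype_format)
            phenotypes = pio.read_phenotypes(config.phenotypes)
        else:
            cohort_config = config.cohort or CohortConfig(seed=config.seed)
            cohort = simulate_cohort(cohort_config)
            samples, phenotypes = cohort.genotypes, cohort.phenotypes
            pio.write_vcf(samples, panel, out / "genotypes.vcf")
            pio.write_phenotypes(phenotypes, out / "phenotypes.tsv")
            (out / "provenance.yaml").write_text(yaml.safe_dump(cohort.provenance))
            logger.info("simulated cohort of %d samples", len(samples))

        results = score_cohort(samples, panel, policy=config.apoe_policy)
        scores = results_to_frame(results, panel)
        n_excluded = int(scores["prs"].isna().sum())
        if n_excluded:
            excluded = scores.loc[scores["prs"].isna(), "sample_id"].tolist()
            logger.warning("%d sample(s) excluded from analysis: %s", n_excluded, excluded)
        pio.write_scores(scores, out / "scores.tsv")

        analysis = analyze_cohort(
            scores,
            phenotypes,
            ldl_threshold=config.ldl_threshold,
            selection_alpha=config.selection_alpha,
            candidates=config.candidates,
            ldl_model_within_comparison=config.ldl_model_within_comparison,
        )
        analysis["excluded_samples"] = n_excluded
        (out / "analysis.json").write_text(json.dumps(analysis, indent=2) + "\n")
        (out / "report.txt").write_text(render_report(analysis))
        (out / "config.yaml").write_text(yaml.safe_dump(_runconfig_dict(config)))
        logger.info("bundle written to %s", out)
    finally:
        root.removeHandler(handler)
        handler.close()
    return {
        "out_dir": str(out),
        "scores": str(out / "scores.tsv"),
        "analysis": analysis,
        "report": str(out / "report.txt"),
    }


def _runconfig_dict(config: RunConfig) -> dict:
    from dataclasses import asdict

    d = asdict(config)
    d["out_dir"] = str(d["out_dir"])
    return d
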