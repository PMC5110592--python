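"""End-to-end orchestration: score -> indicators -> taxometrics + CCFI ->
LCA -> LPA -> report.

A :class:`PipelineConfig` (YAML-loadable) fully determines a run; identical
configs give identical result bundles.  Each stage communicates with the
next only through the bundle dict, and a failed stage aborts with the stage
name while preserving the partial bundle on the raised error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison, indicators, lca, lpa, scoring, synthetic_data, taxometrics
from . import __version__

logger = logging.getLogger("aqstruct.pipeline")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "render_report"]


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names it and ``bundle`` holds partial results."""

    def __init__(self, stage: str, cause: Exception, bundle: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.bundle = bundle


@dataclasses.dataclass
class PipelineConfig:
    """Configuration for a full analysis run."""

    input_csv: str | None = None  # binary item CSV; None -> synthetic six-class data
    input_is_raw: bool = False  # True when the CSV holds 1-4 responses
    synthetic_n: int = 1139
    cutoff: float = 32.0
    impute_method: str = "mode"
    indicator_map_path: str | None = None  # None -> packaged map
    n_cuts: int = 50
    margin: int = 25
    n_windows: int = 25
    overlap: float = 0.9
    tie_reps: int = 10
    n_comparison: int = 100  # B
    k_min: int = 1
    k_max: int = 9
    n_starts: int = 20
    seed: int = 0
    outdir: str = "aqstruct_run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(name: str, bundle: dict):
    """Context manager logging a stage and wrapping failures."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s: failed after %.1fs", name, dt)
                raise PipelineError(name, exc, bundle) from exc
            logger.info("stage %s: done in %.1fs", name, dt)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the result bundle."""
    bundle: dict = {"config": dataclasses.asdict(config), "config_digest": config.digest()}
    with _stage("data", bundle):
        if config.input_csv is not None:
            frame, labels, gender = synthetic_data.read_matrix(config.input_csv)
        else:
            spec = synthetic_data.six_class_spec(config.synthetic_n, seed=config.seed)
            frame, labels, gender = synthetic_data.generate_six_class_items(
                spec, with_gender=True
            )
        bundle["n_input"] = len(frame)
        bundle["gender"] = gender

    with _stage("scoring", bundle):
        if config.input_is_raw:
            key = scoring.load_scoring_key()
            frame, _ = scoring.dichotomize_and_score(frame, key)
        items, impute_report = scoring.impute_missing(
            frame, method=config.impute_method, seed=config.seed
        )
        totals = items.sum(axis=1)
        bundle["impute_report"] = impute_report
        bundle["descriptives"] = scoring.describe_distribution(totals)
        member, base_rate = scoring.assign_putative_taxon(totals, config.cutoff)
        bundle["putative_base_rate"] = base_rate
        bundle["totals"] = totals

    with _stage("indicators", bundle):
        imap = None
        if config.indicator_map_path is not None:
            imap = indicators.load_indicator_item_map(config.indicator_map_path)["indicators"]
        comps = indicators.composites_from_item_map(items, imap)
        bundle["indicators"] = comps
        bundle["validity"] = indicators.indicator_validity(comps, member)

    with _stage("taxometrics", bundle):
        results = comparison.ccfi_analysis(
            comps,
            base_rate=bundle["putative_base_rate"],
            B=config.n_comparison,
            seed=config.seed,
            mambac_kwargs={
                "n_cuts": config.n_cuts,
                "margin": config.margin,
                "tie_reps": config.tie_reps,
            },
            window_kwargs={
                "n_windows": config.n_windows,
                "overlap": config.overlap,
                "tie_reps": config.tie_reps,
            },
        )
        bundle["ccfi"] = {p: r.ccfi for p, r in results.items()}
        bundle["ccfi_labels"] = {p: r.label for p, r in results.items()}
        bundle["ensembles"] = results
        base_rates = {}
        taxo_seed = config.seed + 997
        panels = {
            "MAMBAC": taxometrics.mambac_panel(
                comps, n_cuts=config.n_cuts, margin=config.margin,
                tie_reps=config.tie_reps, seed=taxo_seed,
            ),
            "MAXCOV": taxometrics.maxcov_panel(
                comps, n_windows=config.n_windows, overlap=config.overlap,
                tie_reps=config.tie_reps, seed=taxo_seed,
            ),
            "MAXEIG": taxometrics.maxeig_panel(
                comps, n_windows=config.n_windows, overlap=config.overlap,
                tie_reps=config.tie_reps, seed=taxo_seed,
            ),
            "LMODE": [taxometrics.lmode_analysis(comps).curve],
        }
        for proc, panel in panels.items():
            base_rates[proc] = taxometrics.estimate_base_rates(panel)
        bundle["base_rates"] = base_rates
        bundle["curve_panels"] = panels

    with _stage("lca", bundle):
        n = len(items)
        fits, rows = {}, []
        for k in range(config.k_min, config.k_max + 1):
            fit = lca.fit_lca(items, k, n_starts=config.n_starts, seed=config.seed)
            idx = lca.fit_indices(fit, n)
            fits[k] = fit
            rows.append(
                {"classes": k, "loglik": fit.loglik, "aic": idx.aic, "bic": idx.bic,
                 "ssabic": idx.ssabic, "entropy": idx.entropy}
            )
        table = pd.DataFrame(rows)
        best_k = int(table.loc[table["bic"].idxmin(), "classes"])
        bundle["lca_fit_table"] = table
        bundle["lca_best_k"] = best_k
        bundle["lca_fits"] = fits
        best = fits[best_k]
        bundle["lca_class_summaries"] = lca.class_summaries(best, totals)
        resid = lca.bivariate_residuals(best, items)
        bundle["lca_flagged_pairs"] = int(resid["flagged"].sum())
        if bundle.get("gender") is not None and best.n_classes >= 2:
            try:
                bundle["gender_regression"] = lca.class_covariate_regression(
                    best.assignment, bundle["gender"], reference_class=0
                )
            except RuntimeError as exc:
                bundle["gender_regression"] = {"error": str(exc)}

    with _stage("lpa", bundle):
        fits, rows = {}, []
        for k in range(config.k_min, config.k_max + 1):
            fit = lpa.fit_lpa(comps, k, n_starts=config.n_starts, seed=config.seed)
            idx = lca.fit_indices(fit, len(comps))
            fits[k] = fit
            rows.append(
                {"classes": k, "loglik": fit.loglik, "aic": idx.aic, "bic": idx.bic,
                 "ssabic": idx.ssabic, "entropy": idx.entropy}
            )
        table = pd.DataFrame(rows)
        best_k = int(table.loc[table["bic"].idxmin(), "classes"])
        bundle["lpa_fit_table"] = table
        bundle["lpa_best_k"] = best_k
        bundle["lpa_fits"] = fits
        bundle["agreement"] = lpa.crosstab_agreement(
            bundle["lca_fits"][bundle["lca_best_k"]].assignment, fits[best_k].assignment
        )

    bundle["manifest"] = {
        "package_version": __version__,
        "config_digest": bundle["config_digest"],
        "seed": config.seed,
    }
    return bundle


def render_report(bundle: dict, outdir) -> Path:
    """Write tables (CSV), a text report and comparison-curve figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    missing: list[str] = []
    lines: list[str] = ["aqstruct analysis report", "=" * 40]

    if "manifest" in bundle:
        (out / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=2))
    if "descriptives" in bundle:
        d = bundle["descriptives"]
        lines += [
            f"n = {d.n}, total score mean {d.mean:.2f} (SD {d.sd:.2f}), "
            f"median {d.median:.1f}, range {d.minimum:.0f}-{d.maximum:.0f}",
            f"skew {d.skew:.3f}, excess kurtosis {d.excess_kurtosis:.3f}, "
            f"Shapiro-Wilk p = {d.normality_p:.2e}",
        ]
    else:
        missing.append("descriptives")
    if "ccfi" in bundle:
        lines.append("")
        for proc in comparison.PROCEDURES:
            if proc in bundle["ccfi"]:
                lines.append(
                    f"CCFI {proc}: {bundle['ccfi'][proc]:.3f} ({bundle['ccfi_labels'][proc]})"
                )
            else:
                lines.append(f"CCFI {proc}: absent")
    else:
        missing.append("ccfi")
    if "base_rates" in bundle:
        lines.append("")
        for proc, est in bundle["base_rates"].items():
            lines.append(
                f"base rate {proc}: averaged-curve {est.averaged_curve:.3f}, "
                f"mean {est.mean:.3f} (SD {est.sd:.3f})"
            )
    for key, fname in [
        ("lca_fit_table", "lca_fit.csv"),
        ("lpa_fit_table", "lpa_fit.csv"),
    ]:
        if key in bundle:
            table = bundle[key].sort_values("classes")
            table.to_csv(out / fname, index=False)
            best = int(table.loc[table["bic"].idxmin(), "classes"])
            lines.append(f"{key}: best BIC at {best} classes (-> {fname})")
        else:
            missing.append(key)
    if "lca_class_summaries" in bundle:
        bundle["lca_class_summaries"].to_csv(out / "lca_class_summaries.csv", index=False)
    if "lpa_fits" in bundle and "lpa_best_k" in bundle:
        fit = bundle["lpa_fits"][bundle["lpa_best_k"]]
        rows = []
        for k in range(fit.n_classes):
            row = {"class": k + 1, "share": float(fit.weights[k])}
            for d, name in enumerate(bundle["indicators"].columns):
                row[name] = f"{fit.means[k, d]:.2f} ({fit.mean_se[k, d]:.2f})"
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "lpa_class_means.csv", index=False)
    if "agreement" in bundle:
        ag = bundle["agreement"]
        ag.table.to_csv(out / "lca_lpa_crosstab.csv")
        lines.append(f"LCA/LPA agreement: {100 * ag.overall:.2f}% ({ag.method} matching)")
    if "ensembles" in bundle:
        fig, axes = plt.subplots(2, 2, figsize=(10, 8))
        for ax, proc in zip(axes.ravel(), comparison.PROCEDURES):
            ens = bundle["ensembles"].get(proc)
            if ens is None:
                ax.set_title(f"{proc} (absent)")
                continue
            ens.to_frame().to_csv(out / f"curves_{proc.lower()}.csv", index=False)
            for mean, q25, q75, lo, hi, color, tag in [
                (ens.cat_mean, ens.cat_q25, ens.cat_q75, ens.cat_lo, ens.cat_hi, "tab:blue", "categorical"),
                (ens.dim_mean, ens.dim_q25, ens.dim_q75, ens.dim_lo, ens.dim_hi, "tab:orange", "dimensional"),
            ]:
                ax.fill_between(ens.x, q25, q75, alpha=0.3, color=color, label=f"{tag} mid-50%")
                ax.plot(ens.x, lo, color=color, lw=0.8)
                ax.plot(ens.x, hi, color=color, lw=0.8)
            ax.plot(ens.x, ens.observed_mean, "k:", lw=2, label="observed")
            ax.set_title(f"{proc} (CCFI = {ens.ccfi:.3f})")
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "comparison_curves.png", dpi=120)
        plt.close(fig)
    else:
        missing.append("ensembles")
    if missing:
        lines += ["", "absent bundle members: " + ", ".join(missing)]
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return out
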