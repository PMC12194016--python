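"""End-to-end pipeline: simulate/ingest -> extract -> analyze -> report.

One reproducible entry point (:func:`run_pipeline`) that chains the
stages, routes all randomness through named substreams of a single root
seed, and writes a report bundle: machine-readable CSV/JSON tables
shaped like the classical result tables of a matrix-test process-data
study (item statistics; cluster characteristics; acceleration effects
per cluster; hierarchical regression; IAP mixed model), a human-readable
markdown summary, and a manifest with seeds, versions and checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy.stats as _st

from . import __version__ as _pkg_version
from .io_logs import default_item_bank, read_event_log, read_item_bank, write_event_log, write_item_bank
from .lft_extraction import ExtractionConfig
from .scores import build_feature_table, item_stats
from .stats_analysis import (
    compare_clusters,
    correlation_ci,
    hierarchical_regression,
    iap_mixed_model,
    mediation_path,
    quadratic_tot_effect,
    ward_cluster,
)
from .synthetic_data import GeneratorConfig, generate_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "render_report"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, round-trippable to YAML/JSON.

    Either ``simulate`` is set (synthetic cohort) or ``log_path`` plus
    optionally ``item_bank_path`` point at existing data.
    """

    out_dir: str = "report"
    seed: int = 0
    simulate: GeneratorConfig | None = None
    log_path: str | None = None
    item_bank_path: str | None = None
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    n_boot_mediation: int = 1000
    n_boot_cluster: int = 100
    k_range: tuple[int, int] = (1, 10)
    write_plot: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = GeneratorConfig(**d["simulate"])
        if d.get("extraction") is not None:
            d["extraction"] = ExtractionConfig(**d["extraction"])
        if d.get("k_range") is not None:
            d["k_range"] = tuple(d["k_range"])
        return cls(**d)


def _stage_seeds(root: int) -> dict[str, int]:
    """Named substreams derived from one root seed (kept below 2^31)."""
    names = ["simulate", "cluster_boot", "mediation_boot"]
    ss = np.random.SeedSequence(root)
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(names, children)
    }


def _fmt(x: float, nd: int = 2) -> str:
    return "NA" if x is None or (isinstance(x, float) and not np.isfinite(x)) else f"{x:.{nd}f}"


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full pipeline and write the report bundle.

    Returns the in-memory results dict (tables plus fitted result
    objects).  On a stage failure every file written so far is removed
    and a :class:`PipelineError` naming the stage is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    seeds = _stage_seeds(config.seed)
    stage = "setup"

    def emit(name: str, text_or_df) -> Path:
        path = out / name
        if isinstance(text_or_df, pd.DataFrame):
            text_or_df.to_csv(path, index=False, float_format="%.6g")
        else:
            path.write_text(text_or_df, encoding="utf-8")
        written.append(path)
        return path

    try:
        # --- data stage ---------------------------------------------------
        stage = "simulate" if config.simulate is not None else "ingest"
        if config.simulate is not None:
            sessions, truth, bank = generate_cohort(
                config.simulate, seed=seeds["simulate"]
            )
            write_event_log(sessions, out / "event_log.csv")
            written.append(out / "event_log.csv")
            write_item_bank(bank, out / "item_bank.json")
            written.append(out / "item_bank.json")
            emit("truth.csv", truth.participants.reset_index(drop=True))
        elif config.log_path is not None:
            bank = (
                read_item_bank(config.item_bank_path)
                if config.item_bank_path
                else default_item_bank()
            )
            sessions = read_event_log(config.log_path, bank)
            truth = None
        else:
            raise PipelineError("config needs either a simulate block or a log_path")

        # --- extract stage ------------------------------------------------
        stage = "extract"
        features, long = build_feature_table(sessions, bank, config.extraction)
        emit("features.csv", features.reset_index(names="participant_id"))
        emit("participant_items.csv", long)

        correct = long.pivot(index="participant_id", columns="item_id", values="correct")
        stats = item_stats(correct)
        by_item = long.groupby("item_id")
        positions = {it.item_id: it.position for it in bank}
        n_rules = {it.item_id: it.n_rules for it in bank}
        item_table = pd.DataFrame(
            {
                "item_id": stats.p.index,
                "position": [positions[i] for i in stats.p.index],
                "rules": [n_rules[i] for i in stats.p.index],
                "p": stats.p.values,
                "item_rest_r": stats.item_rest_r.reindex(stats.p.index).values,
                "m_tot": by_item["tot"].mean().reindex(stats.p.index).values,
                "m_onset": by_item["onset"].mean().reindex(stats.p.index).values,
                "m_inter": by_item["inter"].mean().reindex(stats.p.index).values,
                "m_intra": by_item["intra"].mean().reindex(stats.p.index).values,
            }
        ).sort_values("position")
        emit("item_stats.csv", item_table)

        # --- analyze stage ------------------------------------------------
        stage = "analyze"
        complete = features.dropna(subset=["score", "tot", "inter", "onset", "intra"])
        quad = quadratic_tot_effect(complete["score"], complete["tot"])

        clus_data = complete[["score", "inter"]]
        solution = ward_cluster(
            clus_data.to_numpy(),
            k_range=range(config.k_range[0], config.k_range[1] + 1),
            n_boot=config.n_boot_cluster,
            seed=seeds["cluster_boot"],
        )
        # The strategy dichotomy is the two-cluster cut of the Ward tree
        # (the hypotheses concern two strategy groups); the silhouette-
        # selected k is reported as a structure diagnostic alongside.
        import scipy.cluster.hierarchy as _sch

        two_cut = _sch.fcluster(solution.linkage, t=2, criterion="maxclust")
        labels = pd.Series(two_cut, index=complete.index, name="cluster")
        # the cluster with the higher mean score is the structured one
        means = complete.groupby(labels)["score"].mean()
        structured_label = int(means.idxmax())

        cluster_rows = []
        for lab, grp in complete.groupby(labels):
            row = {"cluster": lab, "n": len(grp),
                   "role": "structured" if lab == structured_label else "unstructured"}
            for col in ("score", "onset", "inter", "intra", "tot"):
                row[f"m_{col}"] = grp[col].mean()
                row[f"sd_{col}"] = grp[col].std(ddof=1)
            cluster_rows.append(row)
        cluster_table = pd.DataFrame(cluster_rows)
        emit("cluster_table.csv", cluster_table)

        comparisons = {}
        g_s = complete[labels == structured_label]
        g_u = complete[labels != structured_label]
        for col in ("score", "inter", "rule_jump_score"):
            x_u = g_u[col].dropna()
            x_s = g_s[col].dropna()
            try:
                comparisons[col] = compare_clusters(x_u, x_s)
            except ValueError:
                comparisons[col] = (np.nan,) * 4

        accel_rows = []
        for lab, grp in complete.groupby(labels):
            role = "structured" if lab == structured_label else "unstructured"
            for measure in ("tot", "onset", "inter", "intra"):
                vals = grp[f"accel_{measure}"].dropna()
                if len(vals) < 4 or grp.loc[vals.index, "score"].std() == 0:
                    continue
                t, p = _st.ttest_1samp(vals, 0.0)
                d = vals.mean() / vals.std(ddof=1)
                try:
                    r, _, pr = correlation_ci(vals, grp.loc[vals.index, "score"])
                except ValueError:
                    r, pr = np.nan, np.nan
                accel_rows.append(
                    {
                        "cluster": lab,
                        "role": role,
                        "measure": measure,
                        "delta_m": vals.mean(),
                        "t": t,
                        "p_delta": p,
                        "d": d,
                        "r_score": r,
                        "p_r": pr,
                    }
                )
        accel_table = pd.DataFrame(accel_rows)
        emit("acceleration_table.csv", accel_table)

        structured = complete[labels == structured_label]
        mediation = None
        regression = None
        if len(structured) >= 30:
            med_in = structured[["inter", "intra", "rule_jump_score", "score"]].dropna()
            mediation = mediation_path(
                med_in["inter"],
                med_in["intra"],
                med_in["rule_jump_score"],
                med_in["score"],
                n_boot=config.n_boot_mediation,
                seed=seeds["mediation_boot"],
            )
            regression = hierarchical_regression(
                structured["score"],
                structured["tot"],
                structured["onset"],
                structured["inter"],
                structured["intra"],
            )
            reg_table = pd.DataFrame(
                {
                    "predictor": regression.beta.index,
                    "beta": regression.beta.values,
                    "t": regression.t.values,
                    "p": regression.p.values,
                    "unique_r2_pct": regression.unique_r2.values * 100,
                    "vif": regression.vif.values,
                }
            )
            emit("regression_table.csv", reg_table)

        mixed_rows = []
        for response in ("tot", "inter"):
            sub = long.dropna(subset=[response])
            try:
                rep = iap_mixed_model(
                    sub[response],
                    sub["iap_global"],
                    sub["iap_current"],
                    sub["participant_id"],
                    sub["item_id"],
                )
                mixed_rows.append(
                    {
                        "response": response,
                        "b_global": rep.b_global,
                        "p_global": rep.p_global,
                        "b_current": rep.b_current,
                        "p_current": rep.p_current,
                        "var_participant": rep.var_participant,
                        "var_item": rep.var_item,
                        "var_residual": rep.var_residual,
                    }
                )
            except (RuntimeError, ValueError) as exc:
                warnings.warn(f"IAP mixed model for {response} failed: {exc}")
        iap_table = pd.DataFrame(mixed_rows)
        emit("iap_mixed_model.csv", iap_table)

        results: dict[str, Any] = {
            "config": config,
            "seeds": seeds,
            "n_participants": len(features),
            "item_table": item_table,
            "cronbach_alpha": stats.cronbach_alpha,
            "features": features,
            "long": long,
            "quadratic": quad,
            "cluster": solution,
            "cluster_table": cluster_table,
            "comparisons": comparisons,
            "acceleration_table": accel_table,
            "mediation": mediation,
            "regression": regression,
            "iap_table": iap_table,
            "truth": truth,
        }

        # --- report stage -------------------------------------------------
        stage = "report"
        emit("report.md", render_report(results))
        if config.write_plot:
            try:
                import matplotlib

                matplotlib.use("Agg")
                import matplotlib.pyplot as plt

                fig, ax = plt.subplots(figsize=(5, 4))
                for lab, grp in complete.groupby(labels):
                    ax.scatter(grp["inter"], grp["score"], s=12, alpha=0.7,
                               label=f"cluster {lab} (n={len(grp)})")
                ax.set_xlabel("mean interrule time (s)")
                ax.set_ylabel("test score")
                ax.legend(frameon=False)
                fig.tight_layout()
                fig.savefig(out / "clusters.png", dpi=120)
                plt.close(fig)
                written.append(out / "clusters.png")
            except Exception as exc:  # plotting is best-effort
                warnings.warn(f"cluster plot skipped: {exc}")

        manifest = {
            "package_version": _pkg_version,
            "root_seed": config.seed,
            "stage_seeds": seeds,
            "config": config.to_dict(),
            "outputs": {
                p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in written
            },
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
        )
        return results
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc


def render_report(results: dict[str, Any]) -> str:
    """Markdown summary of a pipeline run (numbers to 2 decimals)."""
    lines = ["# Matrix log-file time analysis", ""]
    lines.append(f"Participants analysed: {results['n_participants']}; "
                 f"root seed {results['config'].seed}.")
    lines.append("")

    lines.append("## Scale statistics")
    lines.append(f"- Cronbach's alpha (score): {_fmt(results['cronbach_alpha'])}")
    q = results["quadratic"]
    lines.append(
        f"- Quadratic ToT effect: beta_quad = {_fmt(q.beta_quadratic)} "
        f"(p = {_fmt(q.p_quadratic, 3)}), R2_quad = {_fmt(q.r2_quadratic * 100)}%, "
        f"delta R2 vs linear = {_fmt(q.delta_r2 * 100)}% "
        f"(F(1, {q.n - 3}) = {_fmt(q.f_change)}, p = {_fmt(q.p_change, 3)})"
    )
    lines.append("")

    sol = results["cluster"]
    lines.append("## Clustering (Ward / Euclidean, silhouette selection)")
    lines.append(
        f"- k = {sol.k_selected}, average silhouette = {_fmt(sol.silhouette)}, "
        f"sizes = {sol.cluster_sizes}, bootstrap co-assignment stability = "
        f"{_fmt(sol.bootstrap_stability)}"
    )
    for col, (t, df, p, d) in results.get("comparisons", {}).items():
        lines.append(
            f"- structured vs unstructured on {col}: t({_fmt(df)}) = {_fmt(t)}, "
            f"p = {_fmt(p, 3)}, d = {_fmt(d)}"
        )
    lines.append("")

    acc = results["acceleration_table"]
    if not acc.empty:
        lines.append("## Acceleration (first-third minus last-third means)")
        for _, row in acc.iterrows():
            lines.append(
                f"- {row['role']}, {row['measure']}: dM = {_fmt(row['delta_m'])} "
                f"(p = {_fmt(row['p_delta'], 3)}), r with score = {_fmt(row['r_score'])} "
                f"(p = {_fmt(row['p_r'], 3)})"
            )
        lines.append("")

    med = results.get("mediation")
    if med is not None:
        lines.append("## Parallel mediation (structured cluster)")
        lines.append(
            f"- fit: chi2({med.df}) = {_fmt(med.chi2)}, p = {_fmt(med.p_chi2, 3)}, "
            f"CFI = {_fmt(med.cfi, 3)}, RMSEA = {_fmt(med.rmsea, 3)}, "
            f"SRMR = {_fmt(med.srmr, 3)}"
        )
        lines.append(
            f"- direct = {_fmt(med.paths['direct'])} "
            f"[{_fmt(med.ci['direct'][0])}, {_fmt(med.ci['direct'][1])}]; "
            f"indirect via intra = {_fmt(med.indirect1)} "
            f"[{_fmt(med.ci['indirect1'][0])}, {_fmt(med.ci['indirect1'][1])}]; "
            f"indirect via jumps = {_fmt(med.indirect2)} "
            f"[{_fmt(med.ci['indirect2'][0])}, {_fmt(med.ci['indirect2'][1])}]; "
            f"total = {_fmt(med.total)}"
        )
        lines.append("")

    reg = results.get("regression")
    if reg is not None:
        lines.append("## Hierarchical regression (structured cluster)")
        lines.append(
            f"- ToT only: R2 = {_fmt(reg.r2_base * 100)}%; ToT + LFT: "
            f"R2 = {_fmt(reg.r2_full * 100)}%, delta R2 = {_fmt(reg.delta_r2 * 100)}% "
            f"(F({reg.df_change[0]}, {reg.df_change[1]}) = {_fmt(reg.f_change)}, "
            f"p = {_fmt(reg.p_change, 3)})"
        )
        for name in reg.beta.index:
            lines.append(
                f"  - {name}: beta = {_fmt(reg.beta[name])}, p = {_fmt(reg.p[name], 3)}, "
                f"unique R2 = {_fmt(reg.unique_r2[name] * 100)}%, "
                f"VIF = {_fmt(reg.vif[name])}"
            )
        lines.append("")

    iap = results["iap_table"]
    if not iap.empty:
        lines.append("## IAP mixed model (crossed random intercepts)")
        for _, row in iap.iterrows():
            lines.append(
                f"- {row['response']}: b_global = {_fmt(row['b_global'])} "
                f"(p = {_fmt(row['p_global'], 3)}), b_current = {_fmt(row['b_current'])} "
                f"(p = {_fmt(row['p_current'], 3)})"
            )
        lines.append("")
    return "\n".join(lines) + "\n"
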