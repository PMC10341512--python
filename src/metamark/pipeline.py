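"""End-to-end orchestration: preprocess → univariate → PLS-DA → ROC →
SVM panel → phenotype correlation, per configured pairwise comparison,
with every result written as delimited text and all seeds logged."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .config import AnalysisConfig
from .correlation import correlation_filter, pearson_by_metabolite
from .io import FeatureTable, write_table
from .plsda import fit_plsda, plsda_accuracy, plsda_q2, plsda_scores_export
from .preprocess import normalize_chain
from .published import COMPARISONS
from .roc import marker_screen, marker_table
from .svm_panel import nested_cv_evaluate
from .univariate import univariate_screen

logger = logging.getLogger("metamark")

__all__ = ["run_pipeline"]


def _comparison_tag(comparison: tuple[str, str]) -> str:
    safe = [g.replace("+", "plus").replace(" ", "").replace("/", "-")
            for g in comparison]
    return f"{safe[0]}_vs_{safe[1]}"


def run_pipeline(config: AnalysisConfig, table: FeatureTable,
                 phenotype: pd.Series | None = None,
                 comparisons: list[tuple[str, str]] | None = None,
                 out_dir: str | Path = "results") -> dict:
    """Run every stage for each pairwise comparison; write one directory.

    Returns {comparison tag: {stage: result}}. All group names are checked
    and fold feasibility validated before any computation starts, so a
    misconfigured run fails fast. Stochastic stages derive their streams
    from ``config.seed``; re-running with the same seed reproduces every
    output byte for byte.
    """
    comparisons = [tuple(c) for c in (comparisons or COMPARISONS)]
    for comparison in comparisons:
        table.require_groups(*comparison)
        counts = table.group_labels.value_counts()
        smallest = int(min(counts[g] for g in comparison))
        if config.svm_outer_folds > smallest:
            raise ValueError(
                f"svm_outer_folds={config.svm_outer_folds} exceeds the "
                f"smallest group size {smallest} in {comparison}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: config_hash=%s seed=%d groups=%s",
                config.config_hash(), config.seed, table.groups())

    tss, tss_log = normalize_chain(table)
    write_table(tss, out_dir / "table_tss.tsv")
    write_table(tss_log, out_dir / "table_tss_log10.tsv")

    bundle: dict[str, dict] = {}
    for ci, comparison in enumerate(comparisons):
        tag = _comparison_tag(comparison)
        cdir = out_dir / tag
        cdir.mkdir(exist_ok=True)
        stage_seed = (config.seed + 104729 * ci) % (2**31 - 1)
        logger.info("comparison %s: stage seed %d", tag, stage_seed)

        uni = univariate_screen(tss, tss_log, comparison,
                                alpha=config.alpha,
                                fc_threshold=config.fc_threshold,
                                equal_var=config.ttest_equal_var)
        write_table(uni, cdir / "univariate.tsv",
                    provenance=f"univariate {tag} seed={config.seed}")

        sub = tss_log.subset_groups(*comparison)
        X = sub.intensities.to_numpy()
        y = sub.group_labels.to_numpy()
        n_comp = min(config.plsda_components,
                     sub.n_samples - 1, sub.n_metabolites)
        model = fit_plsda(X, y, n_comp)
        q2 = plsda_q2(X, y, n_comp, seed=stage_seed)
        acc = plsda_accuracy(X, y, n_comp, seed=stage_seed)
        plsda_metrics = pd.DataFrame(
            [{"n_components": model.n_components,
              "r2": model.r2[-1], "q2": q2[-1], "accuracy": acc}])
        write_table(plsda_metrics, cdir / "plsda_metrics.tsv",
                    provenance=f"plsda {tag} seed={stage_seed}")
        write_table(plsda_scores_export(model, sub.sample_ids),
                    cdir / "plsda_scores.tsv",
                    provenance=f"plsda scores {tag}")

        markers = marker_screen(sub, comparison,
                                auc_threshold=config.auc_threshold,
                                n_boot=config.n_bootstrap, seed=stage_seed)
        write_table(marker_table(markers, uni,
                                 auc_threshold=config.auc_threshold),
                    cdir / "roc_markers.tsv",
                    provenance=f"roc {tag} seed={stage_seed}")

        report = nested_cv_evaluate(
            X, y, positive_label=comparison[0],
            repeats=config.svm_repeats, outer_folds=config.svm_outer_folds,
            inner_folds=config.svm_inner_folds, cost=config.svm_cost,
            max_fraction=config.max_feature_fraction, seed=stage_seed,
            feature_names=sub.metabolite_ids, univariate_p=uni["p_raw"])
        write_table(pd.DataFrame([report.metrics()]),
                    cdir / "panel_metrics.tsv",
                    provenance=f"svm panel metrics {tag} seed={stage_seed}")
        panel = report.panel.join(uni[["fold_change"]])
        write_table(panel, cdir / "panel.tsv",
                    provenance=f"svm panel {tag} seed={stage_seed}")

        stages = {"univariate": uni, "plsda": plsda_metrics,
                  "plsda_model": model, "roc": markers, "panel": report}

        if phenotype is not None:
            corr = pearson_by_metabolite(sub, phenotype.loc[sub.sample_ids])
            flagged = correlation_filter(corr, r_threshold=config.r_threshold,
                                         alpha=config.alpha)
            write_table(corr, cdir / "correlation.tsv",
                        provenance=f"correlation {tag}")
            stages["correlation"] = corr
            stages["correlation_flagged"] = flagged
        bundle[tag] = stages

    logger.info("pipeline done: %d comparison(s) written to %s",
                len(comparisons), out_dir)
    return bundle
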