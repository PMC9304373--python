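"""End-to-end pipeline: simulate a cohort, preprocess, extract, score, test.

`full_run` ties the stages together for a whole simulated group and returns
(and optionally writes) the tidy result tables: per-subject peak measures, the
QC epoch accounting, per-subject bSME values, the planned condition contrasts,
and the repeated-measures model summary.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .erp import assign_conditions, measure_subject
from .generator import CONDITIONS, normative_config, simulate_cohort
from .preprocessing import run_preprocessing
from .sme import bootstrap_sme
from .stats import fit_condition_model, planned_comparisons

logger = logging.getLogger(__name__)

__all__ = ["full_run", "write_tables"]

ROIS = ("left", "midline", "right")


def full_run(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Simulate, preprocess and analyze one group; return all result tables."""
    gen = normative_config(
        config.group, profile=config.profile, n_subjects=config.n_subjects, seed=config.seed
    )
    params = config.preprocessing_params()
    results, qc_rows, sme_rows = [], [], []
    for subject, rec, log in simulate_cohort(gen, config.n_iterations, seed=config.seed):
        epochs, qc = run_preprocessing(rec, params)
        epochs = assign_conditions(epochs)
        table = measure_subject(
            epochs, config.group, subject=subject,
            min_epochs=config.min_epochs, mode=config.extraction_mode,
        )
        results.append(table)
        for row in qc.per_condition.itertuples(index=False):
            qc_rows.append((subject, row.condition, row.n_epochs, row.n_rejected,
                            row.n_retained, row.n_interpolated))
        for cond in CONDITIONS:
            for roi in ROIS:
                r = bootstrap_sme(
                    epochs, cond, roi, config.sme_score, config.group,
                    n_boot=config.sme_n_boot, seed=config.seed + subject,
                )
                sme_rows.append((subject, cond, roi, r.score, r.n_epochs, r.n_boot, r.bsme_uV))
        logger.info("subject %d: %d retained epochs", subject, qc.n_retained)

    results_table = pd.concat(results, ignore_index=True)
    qc_table = pd.DataFrame(
        qc_rows,
        columns=["subject", "condition", "n_epochs", "n_rejected", "n_retained", "n_interpolated"],
    )
    sme_table = pd.DataFrame(
        sme_rows, columns=["subject", "condition", "roi", "score", "n_epochs", "n_boot", "bsme_uV"]
    )

    contrasts = pd.DataFrame(
        [vars(c) for c in planned_comparisons(results_table, "amplitude", component="N")]
    )
    fit = fit_condition_model(results_table, dependent="amplitude", component="N")
    model = fit.anova.assign(dependent=fit.dependent, method=fit.method)
    emm = fit.emmeans.rename_axis("condition").reset_index(name="emmean")
    return {
        "results": results_table,
        "qc": qc_table,
        "sme": sme_table,
        "contrasts": contrasts,
        "model": model,
        "emmeans": emm,
    }


def write_tables(tables: dict[str, pd.DataFrame], config: RunConfig, outdir: str | Path) -> list[Path]:
    """Write every table as CSV with the run configuration echoed in a header."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = "".join(f"# {k}: {v}\n" for k, v in sorted(config.to_dict().items()))
    written = []
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
        written.append(path)
    return written
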