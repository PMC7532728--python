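"""End-to-end orchestration: simulate/load -> fit -> metrics -> report.

Every number in the rendered report is read back from the stage-output
CSVs, so the report can never drift from the artifacts.  Output files
carry a provenance block (config hash, seed, library versions) but no
timestamps — timestamps go to the log — so a fixed seed yields
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .fitting import (
    PARAM_NAMES,
    bootstrap_fit,
    estimate_germination,
    fit_competition_model,
)
from .metrics import summarize_pair
from .reference import REFERENCE_ESTIMATES, REFERENCE_SE, SPECIES_NAMES, TREATMENTS
from .synthetic import make_design, simulate_germination, simulate_seed_production

logger = logging.getLogger(__name__)

__all__ = ["RunReport", "run_pipeline", "table1_check"]


@dataclass
class RunReport:
    summary: pd.DataFrame
    fits: pd.DataFrame
    germination: pd.DataFrame | None
    provenance: dict
    out_dir: Path
    flagged: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flagged


def _config_hash(config: RunConfig) -> str:
    # out_dir is excluded: the same analysis written elsewhere is the same run
    payload = repr(
        {k: v for k, v in vars(config).items() if k != "out_dir"}
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    import scipy
    import statsmodels

    return {
        "package": f"annualcoex {__version__}",
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }


def _write_with_provenance(df: pd.DataFrame, path: Path, prov: dict) -> None:
    path.write_text(df.to_csv(index=False))
    # provenance sidecar keeps the CSVs clean for downstream parsing
    (path.with_suffix(".provenance.json")).write_text(json.dumps(prov, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full analysis described by ``config`` and write all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    rng_root = np.random.SeedSequence(config.seed)
    seed_sim, seed_germ, *seed_boot = [
        int(s.generate_state(1)[0] % (2**31)) for s in rng_root.spawn(2 + 4 * len(config.treatments))
    ]

    if config.mode == "simulate":
        design = make_design(config.design_replicates, treatments=config.treatments)
        table = simulate_seed_production(design, config.params, rng_seed=seed_sim)
        any_params = next(iter(config.params.values()))
        germination = simulate_germination(any_params, rng_seed=seed_germ)
        logger.info("simulate: %d pots, %d germination rows", len(table), len(germination))
        _write_with_provenance(table, out / "seed_production.csv", prov)
        _write_with_provenance(germination, out / "germination.csv", prov)
    else:
        table = pd.read_csv(config.input_seed_production)
        germination = (
            pd.read_csv(config.input_germination) if config.input_germination else None
        )
        logger.info("csv: read %d pot rows", len(table))

    flagged: list[str] = []
    fit_rows = []
    rep_frames = []
    summaries = []
    boot_seed_iter = iter(seed_boot)
    treatments = [t for t in config.treatments if t in set(table["treatment"])]
    for trt in treatments:
        fits = {}
        boots = {}
        for focal in ("i", "j"):
            fit = fit_competition_model(table, focal, trt)
            if not fit.converged:
                flagged.append(f"fit not converged: focal={focal}, treatment={trt}")
            b = bootstrap_fit(table, focal, trt, n_boot=config.n_boot, rng_seed=next(boot_seed_iter))
            fit.bootstrap_mean = b.mean()
            fit.bootstrap_se = b.sd()
            fits[focal], boots[focal] = fit, b
            row = {"treatment": trt, "focal": focal, "loglik": fit.loglik, "converged": fit.converged}
            for k in PARAM_NAMES:
                row[f"{k}_ml"] = fit.estimates[k]
                row[f"{k}_ml_se"] = fit.se[k]
                row[f"{k}_boot"] = fit.bootstrap_mean[k]
                row[f"{k}_boot_se"] = fit.bootstrap_se[k]
            fit_rows.append(row)
            reps = b.replicates.copy()
            reps.insert(0, "replicate", np.arange(1, len(reps) + 1))
            reps.insert(0, "focal", focal)
            reps.insert(0, "treatment", trt)
            rep_frames.append(reps)
        se_method = config.propagation if config.propagation != "mc" else "taylor1"
        summary = summarize_pair(
            fits["i"],
            fits["j"],
            boots["i"] if se_method == "bootstrap" else None,
            boots["j"] if se_method == "bootstrap" else None,
            se_method=se_method,
        )
        summaries.append(summary.to_frame())

    fits_df = pd.DataFrame(fit_rows)
    reps_df = pd.concat(rep_frames, ignore_index=True)
    summary_df = pd.concat(summaries, ignore_index=True)
    _write_with_provenance(fits_df, out / "fits.csv", prov)
    _write_with_provenance(reps_df, out / "replicates.csv", prov)
    _write_with_provenance(summary_df, out / "summary.csv", prov)

    germ_df = None
    if germination is not None:
        germ = estimate_germination(germination)
        germ_df = pd.DataFrame(
            [
                {"species": e.species, "g": e.g, "se": e.se, "germinated": e.germinated, "sown": e.sown}
                for e in germ.values()
            ]
        )
        _write_with_provenance(germ_df, out / "germination_estimates.csv", prov)

    report = render_report(out, rounding=config.rounding, provenance=prov, flagged=flagged)
    (out / "report.md").write_text(report)
    return RunReport(
        summary=summary_df,
        fits=fits_df,
        germination=germ_df,
        provenance=prov,
        out_dir=out,
        flagged=flagged,
    )


_SUMMARY_ROWS = [
    ("rho", "Niche overlap (rho)"),
    ("niche_difference", "Niche difference (1 - rho)"),
    ("demographic_ratio", "Demographic ratio (j/i)"),
    ("competitive_response_ratio", "Competitive response ratio (i/j)"),
    ("fitness_ratio", "Average fitness ratio (kappa_j/kappa_i)"),
    ("igr_i_into_j", "Invasion growth rate, i into j"),
    ("igr_j_into_i", "Invasion growth rate, j into i"),
]


def render_report(out_dir: Path, rounding: int, provenance: dict, flagged: list[str]) -> str:
    """Render report.md strictly from the stage-output CSVs in ``out_dir``."""
    summary = pd.read_csv(out_dir / "summary.csv")
    lines = ["# Coexistence analysis report", ""]
    lines.append(f"Species i = {SPECIES_NAMES['i']} (native), j = {SPECIES_NAMES['j']} (introduced).")
    lines.append("")
    header = "| Quantity | " + " | ".join(summary["treatment"]) + " |"
    lines += [header, "|" + "---|" * (len(summary) + 1)]
    for key, label in _SUMMARY_ROWS:
        cells = [
            f"{round(r[key], rounding)} ({round(r[f'{key}_se'], rounding)})"
            if np.isfinite(r.get(f"{key}_se", np.nan))
            else f"{round(r[key], rounding)}"
            for _, r in summary.iterrows()
        ]
        lines.append(f"| {label} | " + " | ".join(cells) + " |")
    outcome_cells = " | ".join(summary["outcome"])
    lines.append(f"| Interaction outcome | {outcome_cells} |")
    lines += ["", f"SE method: {summary['se_method'].iloc[0]}", ""]
    if flagged:
        lines += ["## Flags", ""] + [f"- {f}" for f in flagged] + [""]
    lines += ["## Provenance", "", "```json", json.dumps(provenance, indent=2, sort_keys=True), "```", ""]
    return "\n".join(lines)


def table1_check(out_dir: str | Path = "results-table1", rounding: int = 2) -> pd.DataFrame:
    """Recompute every derived coexistence quantity from the reference
    point estimates (fitting skipped), with first-order Taylor SEs from the
    published per-parameter SEs (diagonal covariance)."""
    from . import uncertainty
    from .metrics import METRIC_FUNCS, classify_outcome

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for trt in TREATMENTS:
        est = REFERENCE_ESTIMATES[trt]
        se = REFERENCE_SE[trt]
        order = ["lambda_i", "alpha_ii", "alpha_ij", "lambda_j", "alpha_jj", "alpha_ji"]
        x = np.array([est[k] for k in order])
        cov = np.diag(np.array([se[k] for k in order]) ** 2)
        row = {"treatment": trt}
        for name, fn in METRIC_FUNCS.items():
            res = uncertainty.taylor_propagate(fn, x, cov, order=1, name=name)
            row[name] = res.value
            row[f"{name}_se"] = res.sd
        row["outcome"] = classify_outcome(row["rho"], row["fitness_ratio"])
        row["se_method"] = "taylor1"
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out / "summary.csv", index=False)
    return df
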