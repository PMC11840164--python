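"""End-to-end orchestration: phantom -> tensor -> ALPS -> statistics -> mediation.

A single YAML-configurable run simulates diffusion phantoms and a subject
cohort, fits tensors, computes ALPS indices, runs the group-comparison /
ROC / partial-correlation battery and the per-region mediation models, and
writes all artifacts (CSV/JSON plus a human-readable summary) to an output
directory.  Every stage draws its seed deterministically from the master
seed by stable hashing of the stage name, so adding a stage never perturbs
earlier stages' randomness, and two runs from the same config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats as cs
from . import mediation as med
from .alps_index import compute_subject_alps
from .synthetic_data import CohortSpec, PhantomSpec, g_for_alps, generate_cohort, \
    generate_phantom
from .dwi_tensor import fit_volume

logger = logging.getLogger("alpsflow")

FLOAT_FMT = "%.10g"  # 10 significant digits in every CSV for regression-diffing

MEDIATION_COVARIATES = ("age", "sex", "education", "tiv")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed < 2**31 from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "master_seed": 0,
    "phantom": {
        "n_per_group": 2,
        "snr": 30.0,
        "noise": "rician",
        "grid_shape": [12, 12, 12],
        "n_directions": 32,
    },
    "cohort": {},          # overrides for CohortSpec fields
    "analysis": {
        "alpha": 0.05,
        "n_boot": 2000,
        "ci_level": 0.95,
        "mediators": ["anterior_cingulate_gyrus", "orbital_inferior_frontal_gyrus"],
        "yates": False,
    },
}


@dataclass
class RunConfig:
    master_seed: int = 0
    phantom: dict = field(default_factory=lambda: dict(DEFAULT_CONFIG["phantom"]))
    cohort: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=lambda: dict(DEFAULT_CONFIG["analysis"]))
    out_dir: str = "alpsflow_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        cfg = cls()
        cfg.master_seed = int(raw.get("master_seed", cfg.master_seed))
        cfg.out_dir = str(raw.get("out_dir", cfg.out_dir))
        cfg.phantom.update(raw.get("phantom", {}))
        cfg.cohort.update(raw.get("cohort", {}))
        cfg.analysis.update(raw.get("analysis", {}))
        return cfg

    def as_dict(self) -> dict:
        return {"master_seed": self.master_seed, "out_dir": self.out_dir,
                "phantom": self.phantom, "cohort": self.cohort,
                "analysis": self.analysis}


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    routing: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    version: str = ""


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _phantom_stage(cfg: RunConfig, out: Path, report: RunReport) -> None:
    popt = cfg.phantom
    rows = []
    n_failed_fits = 0
    group_alps = {"PD": 1.45, "NC": 1.64}
    for group, target in group_alps.items():
        for i in range(int(popt.get("n_per_group", 2))):
            seed = stage_seed(cfg.master_seed, f"phantom:{group}:{i}")
            spec = PhantomSpec(
                g=g_for_alps(target),
                grid_shape=tuple(popt.get("grid_shape", (12, 12, 12))),
                noise=popt.get("noise", "rician"),
                snr=float(popt.get("snr", 30.0)),
                n_directions=int(popt.get("n_directions", 32)),
                seed=seed,
            )
            dwi, _, rois = generate_phantom(spec)
            tf = fit_volume(dwi)
            n_failed_fits += int((~tf.mask).sum())
            res = compute_subject_alps(tf, rois)
            rows.append({"phantom_id": f"{group}_{i}", "group": group,
                         "alps_truth": target, "seed": seed, **res.as_row()})
    df = pd.DataFrame(rows)
    df.to_csv(out / "alps_phantoms.csv", index=False, float_format=FLOAT_FMT)
    report.counts["phantoms"] = len(df)
    report.counts["phantom_failed_fits"] = n_failed_fits
    report.results["phantom_alps_mean_error"] = float(
        np.mean(np.abs(df["alps_mean"] - df["alps_truth"])))
    report.stages["phantom"] = "ok"


def _cohort_stage(cfg: RunConfig, out: Path, report: RunReport) -> pd.DataFrame:
    spec = CohortSpec(seed=stage_seed(cfg.master_seed, "cohort"),
                      **cfg.cohort)
    cohort, truth = generate_cohort(spec)
    cohort.to_csv(out / "cohort.csv", index=False, float_format=FLOAT_FMT)
    with open(out / "cohort_ground_truth.json", "w") as f:
        json.dump(truth, f, indent=2, default=float)
    report.counts["subjects"] = len(cohort)
    report.counts["subjects_pd"] = int((cohort["group"] == "PD").sum())
    report.counts["subjects_nc"] = int((cohort["group"] == "NC").sum())
    report.stages["cohort"] = "ok"
    return cohort


def _stats_stage(cfg: RunConfig, out: Path, report: RunReport,
                 cohort: pd.DataFrame) -> None:
    alpha = float(cfg.analysis.get("alpha", 0.05))
    rows = []

    # group comparisons of the three ALPS indices, adjusted for age and sex
    covs = cohort[["age", "sex"]].to_numpy()
    for var in ("alps_l", "alps_r", "alps_m"):
        res = cs.gated_group_compare(cohort[var].to_numpy(),
                                     cohort["group"].to_numpy(), covs, alpha)
        report.routing[var] = res.method
        rows.append({"test": f"group_compare:{var}", "method": res.method,
                     "statistic": res.statistic, "p": res.p_value,
                     "p_adjusted": np.nan, "covariates": "age,sex"})

    # sex distribution chi-square
    table = pd.crosstab(cohort["group"], cohort["sex"]).to_numpy()
    chi2, p = cs.chi2_independence(table, yates=bool(cfg.analysis.get("yates", False)))
    rows.append({"test": "chi2:sex", "method": "chi2", "statistic": chi2,
                 "p": p, "p_adjusted": np.nan, "covariates": ""})

    # ROC: NC (higher ALPS) coded positive
    labels = (cohort["group"] == "NC").astype(int).to_numpy()
    auc_rows = []
    for var in ("alps_l", "alps_r", "alps_m"):
        roc = cs.roc_auc(cohort[var].to_numpy(), labels)
        auc_rows.append({"index": var, "auc": roc.auc})
        report.results[f"auc_{var}"] = roc.auc
    pd.DataFrame(auc_rows).to_csv(out / "roc_auc.csv", index=False,
                                  float_format=FLOAT_FMT)

    # partial correlations within the patient group
    pdg = cohort[cohort["group"] == "PD"]
    gmv_cols = [c for c in cohort.columns if c.startswith("gmv_")]

    def pcorr_rows(pairs, covnames, family):
        out_rows = []
        for xcol, ycol in pairs:
            r = cs.partial_correlation(pdg[xcol].to_numpy(), pdg[ycol].to_numpy(),
                                       pdg[list(covnames)].to_numpy())
            out_rows.append({"test": f"pcorr:{xcol}~{ycol}", "method": "partial_corr",
                             "statistic": r.r, "p": r.p_value,
                             "p_adjusted": np.nan, "family": family,
                             "covariates": ",".join(covnames)})
        return out_rows

    rows += pcorr_rows([(f"alps_{h}", "mmse") for h in ("l", "r", "m")],
                       ("age", "sex", "education"), family="alps_mmse")
    rows += pcorr_rows([("alps_m", g) for g in gmv_cols],
                       ("age", "sex", "tiv"), family="alps_gmv")
    rows += pcorr_rows([(g, "mmse") for g in gmv_cols],
                       ("age", "sex", "education", "tiv"), family="gmv_mmse")

    results = pd.DataFrame(rows)
    # BH within each stated correlation family
    for fam in ("alps_gmv", "gmv_mmse"):
        sel = results.get("family") == fam
        if sel.any():
            results.loc[sel, "p_adjusted"] = cs.bh_adjust(results.loc[sel, "p"].to_numpy())
    results.to_csv(out / "statistics.csv", index=False, float_format=FLOAT_FMT)
    for var in ("alps_m",):
        row = results[results["test"] == f"group_compare:{var}"].iloc[0]
        report.results[f"group_F_{var}"] = float(row["statistic"])
        report.results[f"group_p_{var}"] = float(row["p"])
    r_row = results[results["test"] == "pcorr:alps_m~mmse"].iloc[0]
    report.results["partial_r_alps_m_mmse"] = float(r_row["statistic"])
    report.stages["statistics"] = "ok"


def _mediation_stage(cfg: RunConfig, out: Path, report: RunReport,
                     cohort: pd.DataFrame) -> None:
    pdg = cohort[cohort["group"] == "PD"]
    covs = pdg[list(MEDIATION_COVARIATES)].to_numpy()
    n_boot = int(cfg.analysis.get("n_boot", 2000))
    level = float(cfg.analysis.get("ci_level", 0.95))
    rows = []
    for region in cfg.analysis.get("mediators", []):
        col = f"gmv_{region}"
        if col not in cohort.columns:
            raise ValueError(f"mediator region {region!r} not in cohort table")
        seed = stage_seed(cfg.master_seed, f"mediation:{region}")
        res = med.mediate(pdg["alps_m"].to_numpy(), pdg[col].to_numpy(),
                          pdg["mmse"].to_numpy(), covs, n_boot=n_boot,
                          level=level, seed=seed)
        rows.append({"region": region, "a": res.a, "b": res.b, "c": res.c,
                     "c_prime": res.c_prime, "indirect": res.indirect,
                     "ci_lower": res.ci_lower, "ci_upper": res.ci_upper,
                     "proportion_mediated_pct": res.proportion_mediated,
                     "flags": ";".join(res.flags)})
        report.results[f"proportion_mediated_{region}"] = res.proportion_mediated
    pd.DataFrame(rows).to_csv(out / "mediation.csv", index=False,
                              float_format=FLOAT_FMT)
    with open(out / "mediation_meta.json", "w") as f:
        json.dump({"n_boot": n_boot, "ci_level": level,
                   "covariates": list(MEDIATION_COVARIATES),
                   "seeds": {r["region"]: stage_seed(cfg.master_seed,
                                                     f"mediation:{r['region']}")
                             for r in rows}}, f, indent=2)
    report.stages["mediation"] = "ok"


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------

def run_full_pipeline(config: RunConfig) -> RunReport:
    """Run simulate -> fit -> ALPS -> statistics -> mediation end to end.

    All artifacts are written under ``config.out_dir``; any stage failure
    aborts the downstream stages with a named error.
    """
    from . import __version__
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as f:
        yaml.safe_dump(config.as_dict(), f, sort_keys=True)

    report = RunReport(version=__version__)
    stages = [("phantom", _phantom_stage), ("cohort", _cohort_stage),
              ("statistics", _stats_stage), ("mediation", _mediation_stage)]
    cohort = None
    for name, fn in stages:
        try:
            if name in ("statistics", "mediation"):
                fn(config, out, report, cohort)
            elif name == "cohort":
                cohort = fn(config, out, report)
            else:
                fn(config, out, report)
            logger.info("stage %s: ok", name)
        except Exception as exc:
            report.stages[name] = f"failed: {exc}"
            _write_report(out, report)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    _write_report(out, report)
    return report


def _write_report(out: Path, report: RunReport) -> None:
    with open(out / "report.json", "w") as f:
        json.dump({"stages": report.stages, "counts": report.counts,
                   "routing": report.routing, "results": report.results,
                   "version": report.version}, f, indent=2, default=float)
    lines = ["alpsflow run summary", "====================", ""]
    lines += [f"stage {k}: {v}" for k, v in report.stages.items()]
    lines.append("")
    lines += [f"{k} = {v}" for k, v in report.counts.items()]
    lines.append("")
    lines += [f"route {k}: {v}" for k, v in report.routing.items()]
    lines.append("")
    lines += [f"{k} = {v:.10g}" if isinstance(v, float) else f"{k} = {v}"
              for k, v in report.results.items()]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
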