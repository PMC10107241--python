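"""End-to-end study pipeline: validate -> networks -> nulls -> r_com -> models.

Orchestrates the whole workflow over a collection of sites, either
in-memory (lists of flock matrices and covariates) or from a directory of
per-site long-format CSVs plus one covariate table.  Per-site randomness is
derived from a master seed and the site's position, so results are a pure
function of (inputs, config, seed) and independent of execution order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gradients import run_gradient_analysis, screen_predictors
from .io import SiteCovariates, read_flock_matrix, read_site_covariates, validate_site
from .network import FlockMatrix
from .nullmodel import DEFAULT_N_PERM, SignificanceResult, assess_network
from .robustness import DEFAULT_N_BOOT, RCOM_THRESHOLD, RcomResult, rcom

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Study-level knobs; the defaults are the canonical analysis settings:

    at least 10 flocks per analysed site, 3500 permutations per null chain,
    100 bootstrap replicates for r_com, and an r_com > 0.4 robustness
    subset for the modularity regression.
    """

    min_flocks: int = 10
    n_perm: int = DEFAULT_N_PERM
    n_boot: int = DEFAULT_N_BOOT
    rcom_threshold: float = RCOM_THRESHOLD
    subsets: tuple[str, ...] = ("all", "min20", "rcom04")
    min_flocks_subset: int = 20
    seed: int = 0
    proposal: str = "metropolis"


@dataclass(frozen=True)
class PipelineResult:
    significance: list[SignificanceResult]
    rcom_results: list[RcomResult]
    metrics_table: pd.DataFrame
    fits: dict[str, dict]
    summary: dict
    excluded: list[tuple[str, str]]  # (site_id, reason)


def _site_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0]
               % (2**31 - 1))


def run_pipeline(flock_matrices: list[FlockMatrix],
                 covariates: list[SiteCovariates],
                 cfg: PipelineConfig = PipelineConfig(),
                 fit_models: bool = True) -> PipelineResult:
    """Run the full analysis over in-memory site data.

    Sites failing validation (fewer than ``cfg.min_flocks`` flocks) are
    excluded with a reason; per-site failures downstream are isolated, not
    fatal.  Gradient models are fitted for every configured subset when
    at least two analysable sites remain and ``fit_models`` is set.
    """
    if not flock_matrices:
        raise ValueError("no sites provided")
    order = sorted(range(len(flock_matrices)),
                   key=lambda i: flock_matrices[i].site_id)
    significance: list[SignificanceResult] = []
    rcoms: list[RcomResult] = []
    excluded: list[tuple[str, str]] = []
    kept_metrics = []
    for i in order:
        fm = flock_matrices[i]
        report = validate_site(fm, cfg.min_flocks)
        if not report.passed:
            excluded.append((fm.site_id, "; ".join(report.issues)))
            continue
        seed = _site_seed(cfg.seed, i)
        try:
            sig = assess_network(fm, n_perm=cfg.n_perm, seed=seed,
                                 proposal=cfg.proposal)
            rc = rcom(fm, n_boot=cfg.n_boot, seed=seed + 1)
        except Exception as exc:  # isolate per-site failures
            logger.error("%s: site failed (%s)", fm.site_id, exc)
            excluded.append((fm.site_id, f"error: {exc}"))
            continue
        significance.append(sig)
        rcoms.append(rc)
        kept_metrics.append(sig.observed)

    if not significance:
        raise ValueError("no valid sites after filtering")

    kept_ids = {s.site_id for s in significance}
    kept_covars = [c for c in covariates if c.site_id in kept_ids]
    table = _metrics_table(significance, rcoms)

    fits: dict[str, dict] = {}
    if fit_models and len(significance) >= 8:
        for subset in cfg.subsets:
            try:
                fitset = run_gradient_analysis(
                    kept_metrics, kept_covars, subset=subset,
                    rcom_results=rcoms, rcom_threshold=cfg.rcom_threshold,
                    min_flocks=cfg.min_flocks_subset)
            except ValueError as exc:
                logger.warning("subset %s not fitted: %s", subset, exc)
                continue
            fits[subset] = {
                resp: {
                    "family": f.spec.family,
                    "transform": f.spec.transform,
                    "n": f.n_sites,
                    "interaction_retained": f.interaction_retained,
                    "convergence": f.convergence,
                    "coefficients": f.coefficients.to_dict(orient="records"),
                    "vifs": f.vifs,
                } for resp, f in fitset.items()
            }

    n_cv_sig = sum(s.cv_significant for s in significance)
    summary = {
        "n_sites_input": len(flock_matrices),
        "n_sites_analysed": len(significance),
        "n_sites_excluded": len(excluded),
        "n_cv_significant": n_cv_sig,
        "frac_cv_significant": n_cv_sig / len(significance),
        "n_min20": int((table["n_flocks"] >= cfg.min_flocks_subset).sum()),
        "n_rcom_retained": int(sum(r.r_com > cfg.rcom_threshold
                                   and not r.degenerate for r in rcoms)),
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "n_boot": cfg.n_boot,
    }
    _check_consistency(summary, significance, table)
    return PipelineResult(significance=significance, rcom_results=rcoms,
                          metrics_table=table, fits=fits, summary=summary,
                          excluded=excluded)


def _metrics_table(significance: list[SignificanceResult],
                   rcoms: list[RcomResult]) -> pd.DataFrame:
    ri = {r.site_id: r for r in rcoms}
    rows = []
    for s in significance:
        m = s.observed
        rows.append({
            "site_id": m.site_id, "n_species": m.n_species,
            "n_flocks": m.n_flocks,
            "mean_richness_per_flock": m.mean_richness_per_flock,
            "cv": m.cv, "cv_pvalue": s.cv_pvalue,
            "cv_significant": s.cv_significant,
            "avg_degree_norm": m.avg_degree_norm,
            "connectance": m.connectance,
            "modularity_q": m.modularity_q,
            "clustering": m.clustering,
            "r_com": ri[m.site_id].r_com if m.site_id in ri else np.nan,
            **{f"verdict_{k}": v for k, v in s.envelope_verdicts.items()},
        })
    return pd.DataFrame(rows)


def _check_consistency(summary: dict, significance, table: pd.DataFrame) -> None:
    assert summary["n_sites_analysed"] == len(table)
    assert summary["n_cv_significant"] == int(table["cv_significant"].sum())


def run_pipeline_dir(data_dir: str | Path, covars_path: str | Path,
                     cfg: PipelineConfig = PipelineConfig(),
                     out_dir: str | Path | None = None) -> PipelineResult:
    """Run the pipeline over a directory of per-site long CSVs.

    Every ``*.csv`` in ``data_dir`` (except the covariate table itself) is
    read as one site; results are optionally written to ``out_dir`` as
    metrics.csv, significance.json, rcom.csv, fits.json and summary.json.
    """
    data_dir = Path(data_dir)
    covars = read_site_covariates(covars_path)
    files = sorted(p for p in data_dir.glob("*.csv")
                   if p.resolve() != Path(covars_path).resolve())
    if not files:
        raise ValueError(f"no site files in {data_dir}")
    fms = [read_flock_matrix(p, dialect="long") for p in files]
    result = run_pipeline(fms, covars, cfg)
    if out_dir is not None:
        write_results(result, out_dir, cfg)
    return result


def write_results(result: PipelineResult, out_dir: str | Path,
                  cfg: PipelineConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.metrics_table.to_csv(out / "metrics.csv", index=False)
    sig = [{
        "site_id": s.site_id, "cv_pvalue": s.cv_pvalue,
        "cv_significant": bool(s.cv_significant),
        "envelope_verdicts": s.envelope_verdicts,
        "n_perm": s.n_perm, "seed": s.seed,
        "missing_counts": s.missing_counts,
    } for s in result.significance]
    (out / "significance.json").write_text(json.dumps(sig, indent=2))
    pd.DataFrame([{"site_id": r.site_id, "r_com": r.r_com,
                   "n_boot": r.n_boot, "degenerate": r.degenerate}
                  for r in result.rcom_results]).to_csv(out / "rcom.csv",
                                                        index=False)
    (out / "fits.json").write_text(json.dumps(result.fits, indent=2))
    (out / "summary.json").write_text(json.dumps(
        {**result.summary, "config": asdict(cfg),
         "excluded": result.excluded}, indent=2))
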