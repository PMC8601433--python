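"""Pipeline driver: generate → reduce → invert → fit → regress → compare.

The stages are ordinary library calls; this module sequences them over a
phantom grid, writes every stage's outputs (CSV/JSON, optional figures), and
provides the (a, b)-space comparison of phantom scattering parameters with
tissue values supplied by the user as a small CSV table
(``label,a_cm1,b,source``) — tissue parameters are consumed, never bundled
as ground truth.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import build_calibration, build_instrument, load_config
from .phantom_model import PhantomRecipe
from .spectral_fit import (
    RegressionLine,
    concentration_regression,
    fit_absorption,
    fit_scattering,
)
from .sphere_reduction import (
    coefficient_of_variation,
    invert_repeats,
    propagate_uncertainty,
)
from .synthetic_data import simulate_phantom_grid, simulate_ps_bead_set

__all__ = [
    "analyze_phantom_records",
    "run_pipeline",
    "compare_to_tissue",
    "load_tissue_table",
]

CSV_FLOAT_FORMAT = "%.12g"  # round-trips doubles at 12 significant digits


def _nan_sem(x: np.ndarray) -> np.ndarray:
    """Per-column standard error of the mean over the valid (finite) repeats."""
    nvalid = np.sum(np.isfinite(x), axis=0)
    out = np.full(x.shape[1], np.nan)
    ok = nvalid >= 2
    if ok.any():
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(x[:, ok], axis=0, ddof=1)
        out[ok] = sd / np.sqrt(nvalid[ok])
    return out


def analyze_phantom_records(
    records: list[dict],
    g: float = 0.5,
    weighted: bool = True,
    budget: bool = False,
    u_thickness_cm: float = 0.005,
    u_rho: float = 0.005,
    u_n: float = 0.005,
) -> tuple[pd.DataFrame, list[dict]]:
    """Invert and fit a list of simulated (or loaded) phantom records.

    For each record: every repeat is inverted separately, coefficients are
    averaged across repeats, and the four characterization parameters are
    fitted (inverse-variance weighted by the repeat spread when ``weighted``).
    Returns the per-phantom fit table and a per-phantom detail list
    (spectra, CoV, budget).
    """
    rows = []
    details = []
    for idx, rec in enumerate(records):
        record = rec["record"]
        truth = rec["truth"]
        lam = record.wavelengths
        results = invert_repeats(record, g=g, n=truth.n)
        mu_a = np.vstack([r.mu_a for r in results])
        mu_sp = np.vstack([r.mu_s_prime for r in results])
        # repeats at individual wavelengths can fail or not converge (e.g.
        # noisy R + T > 1 in the near-transparent regime, where the residual
        # is dumped into the coefficients); statistics use the converged ones
        conv = np.vstack([r.converged for r in results])
        mu_a = np.where(conv, mu_a, np.nan)
        mu_sp = np.where(conv, mu_sp, np.nan)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_a, mean_s = np.nanmean(mu_a, axis=0), np.nanmean(mu_sp, axis=0)
        nrep = record.n_repeats
        if nrep >= 2:
            u_a = _nan_sem(mu_a)
            u_s = _nan_sem(mu_sp)
            cov_a, cov_s = coefficient_of_variation(results)
        else:
            u_a = u_s = None
            cov_a = cov_s = np.full_like(lam, np.nan)
        bud = None
        if budget:
            bud = propagate_uncertainty(
                record, g=g, n=truth.n,
                u_thickness_cm=u_thickness_cm, u_rho=u_rho, u_n=u_n,
                repeat_results=results,
            )
            u_a, u_s = bud.combined_k1_mu_a, bud.combined_k1_mu_s_prime

        mask_a = np.isfinite(mean_a)
        mask_s = np.isfinite(mean_s) & (mean_s > 0)

        def usable(u, mask):
            if not weighted or u is None:
                return None
            u = np.asarray(u)[mask]
            if np.any(~np.isfinite(u)) or np.any(u <= 0):
                return None
            return u

        fa = fit_absorption(lam[mask_a], mean_a[mask_a], usable(u_a, mask_a))
        fs = fit_scattering(lam[mask_s], mean_s[mask_s], usable(u_s, mask_s))
        recipe: PhantomRecipe = rec["recipe"]
        rows.append(
            {
                "phantom_id": idx,
                "tdp_pct": recipe.tdp_pct,
                "cbp_pct": recipe.cbp_pct,
                "ps_pct": recipe.ps_pct,
                "a": fs.a, "u_a": fs.u_a, "b": fs.b, "u_b": fs.u_b,
                "cod_s": fs.cod,
                "c": fa.c, "u_c": fa.u_c, "d": fa.d, "u_d": fa.u_d,
                "cod_a": fa.cod,
                "n_converged": int(np.sum([r.converged.sum() for r in results])),
                "n_points": int(lam.size * nrep),
            }
        )
        details.append(
            {
                "wavelengths": lam, "mu_a": mean_a, "mu_s_prime": mean_s,
                "u_mu_a": u_a, "u_mu_s_prime": u_s,
                "cov_mu_a_pct": cov_a, "cov_mu_s_prime_pct": cov_s,
                "n_converged_repeats": conv.sum(axis=0),
                "budget": bud, "truth": truth, "recipe": recipe,
                "results": results,
            }
        )
    return pd.DataFrame(rows), details


def load_tissue_table(path: str | Path) -> pd.DataFrame:
    """Read a tissue parameter table CSV: label,a_cm1,b[,source]."""
    df = pd.read_csv(path)
    required = {"label", "a_cm1", "b"}
    if not required.issubset(df.columns):
        raise ValueError(f"tissue table must have columns {sorted(required)}")
    if "source" not in df.columns:
        df["source"] = ""
    if (df["a_cm1"] <= 0).any():
        raise ValueError("tissue a values must be positive")
    return df


def compare_to_tissue(
    fits: pd.DataFrame,
    tissue: pd.DataFrame,
    scale_a: float = 10.0,
    scale_b: float = 0.5,
    b_margin: float = 0.05,
) -> dict:
    """Compare phantom (a, b) scattering parameters with tissue values.

    Distances are Euclidean after scaling a by ``scale_a`` (1/cm) and b by
    ``scale_b``. Tissues with b above the phantom-achievable maximum are
    flagged as needing sub-wavelength (Rayleigh-regime) scatterers; those
    below the minimum as needing larger particles (e.g. micrometre beads).
    """
    if fits.empty or tissue.empty:
        raise ValueError("fits and tissue table must be non-empty")
    pa, pb = fits["a"].to_numpy(), fits["b"].to_numpy()
    rows = []
    for _, trow in tissue.iterrows():
        dist = np.sqrt(
            ((pa - trow["a_cm1"]) / scale_a) ** 2 + ((pb - trow["b"]) / scale_b) ** 2
        )
        k = int(np.argmin(dist))
        flag = ""
        if trow["b"] > pb.max() + b_margin:
            flag = "b above phantom range: needs sub-wavelength scatterers"
        elif trow["b"] < pb.min() - b_margin:
            flag = "b below phantom range: needs larger particles"
        rows.append(
            {
                "label": trow["label"],
                "tissue_a_cm1": trow["a_cm1"],
                "tissue_b": trow["b"],
                "nearest_phantom_id": int(fits.iloc[k]["phantom_id"]),
                "distance": float(dist[k]),
                "flag": flag,
            }
        )
    per_tissue = pd.DataFrame(rows)
    per_phantom = []
    ta, tb = tissue["a_cm1"].to_numpy(), tissue["b"].to_numpy()
    for _, prow in fits.iterrows():
        dist = np.sqrt(
            ((ta - prow["a"]) / scale_a) ** 2 + ((tb - prow["b"]) / scale_b) ** 2
        )
        k = int(np.argmin(dist))
        per_phantom.append(
            {
                "phantom_id": int(prow["phantom_id"]),
                "a": prow["a"], "b": prow["b"],
                "nearest_tissue": tissue.iloc[k]["label"],
                "distance": float(dist[k]),
            }
        )
    coverage = float(np.mean(per_tissue["flag"] == ""))
    return {
        "per_tissue": per_tissue,
        "per_phantom": pd.DataFrame(per_phantom),
        "coverage_fraction": coverage,
    }


def _regression_to_jsonable(reg: dict) -> dict:
    def line(v):
        if isinstance(v, RegressionLine):
            return asdict(v) | {
                "slope_consistent_with_zero": v.slope_consistent_with_zero
            }
        if isinstance(v, dict):
            return {str(k): line(x) for k, x in v.items()}
        return v

    return {k: line(v) for k, v in reg.items()}


def run_pipeline(
    config: str | Path | dict | None = None,
    out_dir: str | Path = "phantom_run",
    figures: bool = True,
) -> dict:
    """Run the full synthetic characterization pipeline and write outputs.

    Outputs under ``out_dir``: the resolved config and its hash, per-phantom
    reduced and inverted spectra (CSV), the four-parameter fit table, the
    concentration-regression report (JSON), optional tissue comparison, and
    best-effort summary figures. Re-running the same config reproduces
    byte-identical CSVs.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    t_start = time.time()

    cfg_text = json.dumps(cfg, sort_keys=True, default=str)
    cfg_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]
    (out / "config.json").write_text(cfg_text)

    def stage(name):
        log.append(f"{name} @ {time.time() - t_start:.1f}s")

    instrument = build_instrument(cfg)
    calibration = build_calibration(cfg)
    rec_cfg = cfg["recipes"]
    inv_cfg = cfg["inversion"]

    stage("generate")
    if instrument.n_repeats == 1:
        log.append("warning: n_repeats = 1, budget lacks repeatability component")
    pairs = rec_cfg["pairs"]
    pairs = [tuple(p) for p in pairs] if pairs else None
    records = simulate_phantom_grid(
        rec_cfg["tdp_levels"], rec_cfg["cbp_levels"], instrument, calibration,
        pairs=pairs,
    )
    if rec_cfg.get("include_ps_set"):
        records += simulate_ps_bead_set(instrument, calibration)

    manifest = {
        "config_hash": cfg_hash,
        "phantoms": [
            {"phantom_id": i, "seed": r["seed"], **asdict(r["recipe"])}
            for i, r in enumerate(records)
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    stage("reduce")
    for i, r in enumerate(records):
        rec = r["record"]
        df = pd.DataFrame({"wavelength_nm": rec.wavelengths, "R_d": rec.R_d, "T_d": rec.T_d})
        for k in range(rec.n_repeats):
            df[f"R_rep{k}"] = rec.R_repeats[k]
            df[f"T_rep{k}"] = rec.T_repeats[k]
        df.to_csv(out / f"reduced_{i:02d}.csv", index=False, float_format=CSV_FLOAT_FORMAT)

    stage("invert+fit")
    fits, details = analyze_phantom_records(
        records, g=inv_cfg["g"], weighted=cfg["fitting"]["weighted"],
        budget=inv_cfg["budget"], u_thickness_cm=inv_cfg["u_thickness_cm"],
        u_rho=inv_cfg["u_rho"], u_n=inv_cfg["u_n"],
    )
    for i, det in enumerate(details):
        df = pd.DataFrame(
            {
                "wavelength_nm": det["wavelengths"],
                "mu_a_cm1": det["mu_a"],
                "u_mu_a_cm1": det["u_mu_a"] if det["u_mu_a"] is not None else np.nan,
                "mu_s_prime_cm1": det["mu_s_prime"],
                "u_mu_s_prime_cm1": det["u_mu_s_prime"] if det["u_mu_s_prime"] is not None else np.nan,
                "cov_mu_a_pct": det["cov_mu_a_pct"],
                "cov_mu_s_prime_pct": det["cov_mu_s_prime_pct"],
                "n_converged_repeats": det["n_converged_repeats"],
            }
        )
        df.to_csv(out / f"inverted_{i:02d}.csv", index=False, float_format=CSV_FLOAT_FORMAT)
        bud = det["budget"]
        if bud is not None:
            bdf = pd.DataFrame({"wavelength_nm": bud.wavelengths})
            for name, comp in bud.components_mu_a.items():
                bdf[f"u_mu_a_{name}"] = comp
            for name, comp in bud.components_mu_s_prime.items():
                bdf[f"u_mu_s_prime_{name}"] = comp
            bdf["combined_k1_mu_a"] = bud.combined_k1_mu_a
            bdf["combined_k1_mu_s_prime"] = bud.combined_k1_mu_s_prime
            bdf.to_csv(out / f"budget_{i:02d}.csv", index=False, float_format=CSV_FLOAT_FORMAT)
    fits.to_csv(out / "fits.csv", index=False, float_format=CSV_FLOAT_FORMAT)

    stage("regress")
    tdp_only = fits[fits["ps_pct"] == 0]
    regression = None
    if tdp_only["tdp_pct"].nunique() >= 3 and tdp_only["cbp_pct"].nunique() >= 3:
        regression = concentration_regression(
            tdp_only["tdp_pct"], tdp_only["cbp_pct"],
            tdp_only["a"], tdp_only["b"], tdp_only["c"], tdp_only["d"],
        )
        (out / "regression.json").write_text(
            json.dumps(_regression_to_jsonable(regression), indent=1)
        )
    else:
        log.append("regress skipped: fewer than 3 distinct levels per additive")

    stage("compare")
    comparison = None
    if cfg["tissue"]["table"]:
        tissue = load_tissue_table(cfg["tissue"]["table"])
        comparison = compare_to_tissue(
            fits, tissue, scale_a=cfg["tissue"]["scale_a"], scale_b=cfg["tissue"]["scale_b"]
        )
        comparison["per_tissue"].to_csv(
            out / "tissue_comparison.csv", index=False, float_format=CSV_FLOAT_FORMAT
        )

    if figures:
        stage("figures")
        _render_figures(out, details, fits)

    stage("done")
    (out / "run.log").write_text("\n".join(log) + "\n")
    return {
        "fits": fits,
        "details": details,
        "regression": regression,
        "comparison": comparison,
        "manifest": manifest,
        "out_dir": out,
    }


def _render_figures(out: Path, details: list[dict], fits: pd.DataFrame) -> None:
    """Best-effort summary plots (spectra, CoV, parameter scatter)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for det in details:
        lam = det["wavelengths"]
        axes[0, 0].plot(lam, det["mu_a"], lw=0.8)
        axes[0, 1].plot(lam, det["mu_s_prime"], lw=0.8)
        axes[1, 0].plot(lam, det["cov_mu_a_pct"], lw=0.8)
        axes[1, 1].plot(lam, det["cov_mu_s_prime_pct"], lw=0.8)
    axes[0, 0].set_ylabel(r"$\mu_a$ (cm$^{-1}$)")
    axes[0, 1].set_ylabel(r"$\mu_s'$ (cm$^{-1}$)")
    axes[1, 0].set_ylabel(r"CoV $\mu_a$ (%)")
    axes[1, 1].set_ylabel(r"CoV $\mu_s'$ (%)")
    for ax in axes.flat:
        ax.set_xlabel("wavelength (nm)")
    fig.tight_layout()
    fig.savefig(out / "spectra.png", dpi=110)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(fits["a"], fits["b"], xerr=fits["u_a"], yerr=fits["u_b"], fmt="o")
    ax.set_xlabel(r"$a$ (cm$^{-1}$)")
    ax.set_ylabel(r"$b$")
    fig.tight_layout()
    fig.savefig(out / "ab_space.png", dpi=110)
    plt.close(fig)
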