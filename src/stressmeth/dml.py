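"""Differential-methylation calling.

Per-probe ordinary least squares of M-values on the continuous stress score
(adjusting for age and batch), empirical-Bayes moderation of the residual
variances, signed z-scores from the moderated p-values, a spatial HMM whose
posterior null probabilities (LIS) are averaged into the FDR-controlling aLIS
statistic, Pearson-correlation direction classification on the beta scale,
and proximity flagging against a SNP/mQTL position table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import MethylationMatrix
from .errors import ConfigurationError, PipelineError
from .hmm import HmmModel, fit_hmm_lis

log = logging.getLogger(__name__)

_VAR_FLOOR = 1e-20
_P_FLOOR = 1e-300


def build_design(samples: pd.DataFrame) -> pd.DataFrame:
    """Design matrix: intercept, stress score, age, batch indicator(s)."""
    x = pd.DataFrame({"intercept": 1.0, "lsi_score": samples["lsi_score"].to_numpy(float),
                      "age": samples["age"].to_numpy(float)})
    dummies = pd.get_dummies(samples["batch"], prefix="batch", drop_first=True, dtype=float)
    x = pd.concat([x, dummies.reset_index(drop=True)], axis=1)
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # name the columns whose removal restores full rank
        bad = []
        arr = x.to_numpy()
        for j, name in enumerate(x.columns):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(name)
        raise PipelineError(f"design matrix is rank deficient; collinear columns: {bad}")
    return x


def fit_locus_models(m_matrix: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """OLS per probe; returns coef (stress-score slope), se, sigma2, df,
    raw t and two-sided p.  Probes with zero residual variance get NaN p."""
    x = build_design(samples)
    xa = x.to_numpy()
    n, k = xa.shape
    if m_matrix.shape[1] != n:
        raise PipelineError("M-value matrix and sample sheet sample counts differ")
    y = m_matrix.to_numpy(float).T  # samples x probes
    xtx_inv = np.linalg.inv(xa.T @ xa)
    coefs = xtx_inv @ (xa.T @ y)  # k x probes
    resid = y - xa @ coefs
    df = n - k
    if df <= 0:
        raise PipelineError("no residual degrees of freedom")
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / df
    j = x.columns.get_loc("lsi_score")
    b = coefs[j]
    se = np.sqrt(np.maximum(sigma2, 0.0) * xtx_inv[j, j])
    degenerate = sigma2 < _VAR_FLOOR
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, np.nan, b / se)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    if degenerate.any():
        log.warning("%d probes have zero residual variance; p set to NA", int(degenerate.sum()))
    return pd.DataFrame(
        {
            "probe_id": m_matrix.index,
            "coef": b,
            "se": se,
            "sigma2": sigma2,
            "df": float(df),
            "t": t,
            "p": p,
        }
    ).set_index("probe_id")


def _trigamma_inverse(x: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled inverse chi-square prior to the
    residual variances: returns (prior df d0, prior variance s0^2).

    Moments are taken on log variances; when the excess spread of log s^2
    over its sampling variability is non-positive, d0 is infinite and every
    posterior variance collapses to s0^2.
    """
    s2 = sigma2[np.isfinite(sigma2) & (sigma2 > 0)]
    if len(s2) < 10:
        raise PipelineError("fewer than 10 usable probes; variance prior is unstable")
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0.0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderate_variances(stats_df: pd.DataFrame, prior_df: float | None = None) -> pd.DataFrame:
    """Empirical-Bayes shrinkage of residual variances toward the prior;
    moderated t uses the posterior variance and df + d0 degrees of freedom.

    ``prior_df`` overrides the estimated d0 (0 reproduces the raw t;
    infinity equalises all posterior variances at s0^2).
    """
    out = stats_df.copy()
    sigma2 = out["sigma2"].to_numpy(float)
    df = float(out["df"].iloc[0])
    d0, s0_sq = estimate_prior(sigma2, df)
    if prior_df is not None:
        d0 = float(prior_df)
    if np.isinf(d0):
        post = np.full_like(sigma2, s0_sq)
        total_df = np.inf
    elif d0 == 0.0:
        post = sigma2.copy()
        total_df = df
    else:
        post = (d0 * s0_sq + df * sigma2) / (d0 + df)
        total_df = df + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.sqrt(post / sigma2)
        t_mod = np.where(sigma2 < _VAR_FLOOR, np.nan, out["t"].to_numpy() / scale)
    p_mod = 2.0 * stats.t.sf(np.abs(t_mod), total_df)
    out["t_mod"] = t_mod
    out["p_mod"] = p_mod
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    return out


def p_to_z(p: np.ndarray | float, coefficient_sign: np.ndarray | float) -> np.ndarray | float:
    """Signed z: z = sign(b) * Phi^-1(1 - p/2); the sign keeps positive and
    negative effects distinguishable to the HMM's mixture emission."""
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any(~np.isfinite(p_arr)) or np.any(p_arr <= 0) or np.any(p_arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    sign = np.sign(np.atleast_1d(np.asarray(coefficient_sign, dtype=float)))
    sign = np.where(sign == 0, 1.0, sign)
    z = sign * stats.norm.isf(np.clip(p_arr, _P_FLOOR, 1.0) / 2.0)
    return z if np.ndim(p) else float(z[0])


def adjust_lis(lis: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """aLIS at rank k is the running mean of the k smallest LIS values;
    probes with aLIS < alpha are called.  The called set is always a prefix
    of the ascending-LIS ranking (ties broken by input order, i.e. genomic
    order)."""
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must lie in (0, 1)")
    lis = np.asarray(lis, dtype=float)
    if np.any(lis < 0) or np.any(lis > 1):
        raise ConfigurationError("LIS values must lie in [0, 1]")
    order = np.argsort(lis, kind="stable")
    csum = np.cumsum(lis[order])
    alis_sorted = csum / np.arange(1, len(lis) + 1)
    alis = np.empty_like(lis)
    alis[order] = alis_sorted
    return pd.DataFrame({"lis": lis, "alis": alis, "called": alis < alpha})


def classify_direction(
    beta_matrix: pd.DataFrame,
    samples: pd.DataFrame,
    called_probes: list[str] | pd.Index,
    coefs: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson correlation between each called probe's beta row and the
    stress score; direction is the sign of r (r = 0 or a zero-variance row
    falls back to the regression-coefficient sign, with a warning)."""
    lsi = samples["lsi_score"].to_numpy(float)
    lsi_c = lsi - lsi.mean()
    denom_l = np.sqrt((lsi_c**2).sum())
    rows = []
    for pid in called_probes:
        b = beta_matrix.loc[pid].to_numpy(float)
        bc = b - b.mean()
        denom_b = np.sqrt((bc**2).sum())
        if denom_b == 0.0:
            fallback = float(coefs.loc[pid]) if coefs is not None else 0.0
            log.warning("probe %s has zero beta variance; direction from coefficient", pid)
            r = 0.0
            direction = "positive" if fallback >= 0 else "negative"
        else:
            r = float(bc @ lsi_c / (denom_b * denom_l))
            if r == 0.0:
                log.warning("probe %s has r exactly 0; assigned positive", pid)
            direction = "positive" if r >= 0 else "negative"
        rows.append((pid, r, direction))
    return pd.DataFrame(rows, columns=["probe_id", "pearson_r", "direction"]).set_index(
        "probe_id"
    )


def mqtl_proximity(
    dml_calls: pd.DataFrame, snp_table: pd.DataFrame, max_distance: int = 200
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flag probes with a SNP within ``max_distance`` bp on the same
    chromosome (boundary inclusive).  ``dml_calls`` must carry chrom/pos.

    Returns the table with an ``mqtl_near`` column plus near/far counts over
    the called probes.
    """
    if max_distance < 0:
        raise ConfigurationError("max_distance must be >= 0")
    snp_pos: dict[str, np.ndarray] = {}
    for row in snp_table.itertuples(index=False):
        try:
            chrom, pos = str(row.chrom), int(row.pos)
            if pos < 1:
                raise ValueError
        except (TypeError, ValueError):
            log.warning("skipping malformed SNP record: %r", tuple(row))
            continue
        snp_pos.setdefault(chrom, []).append(pos)  # type: ignore[arg-type]
    snp_pos = {c: np.sort(np.asarray(v)) for c, v in snp_pos.items()}
    near = np.zeros(len(dml_calls), dtype=bool)
    for i, row in enumerate(dml_calls.itertuples(index=False)):
        positions = snp_pos.get(str(row.chrom))
        if positions is None or len(positions) == 0:
            continue
        j = np.searchsorted(positions, row.pos)
        dist = min(
            abs(int(positions[j]) - int(row.pos)) if j < len(positions) else np.inf,
            abs(int(positions[j - 1]) - int(row.pos)) if j > 0 else np.inf,
        )
        near[i] = dist <= max_distance
    out = dml_calls.copy()
    out["mqtl_near"] = near
    called = out["called"].to_numpy(bool) if "called" in out else np.ones(len(out), bool)
    summary = {
        "near": int((near & called).sum()),
        "far": int((~near & called).sum()),
    }
    return out, summary


@dataclass
class DmlResult:
    """Full per-probe table plus the fitted HMM and summary counts."""

    table: pd.DataFrame
    model: HmmModel
    d0: float
    s0_sq: float
    mqtl_summary: dict[str, int] | None = None

    @property
    def called(self) -> pd.DataFrame:
        return self.table[self.table["called"]]


def call_dmls(
    matrix: MethylationMatrix,
    manifest: pd.DataFrame,
    samples: pd.DataFrame,
    m_matrix: pd.DataFrame | None = None,
    alpha: float = 0.05,
    snp_table: pd.DataFrame | None = None,
    mqtl_distance: int = 200,
    seed: int = 0,
    hmm_restarts: int = 3,
) -> DmlResult:
    """End-to-end DML calling on a filtered methylation matrix.

    Probes are ordered by (chromosome, position) before the HMM stage; probes
    whose regression is degenerate (zero residual variance) are excluded from
    the HMM with a warning and never called.
    """
    from .preprocess import beta_to_m

    if m_matrix is None:
        m_matrix = beta_to_m(matrix)
    man = manifest.set_index("probe_id").loc[matrix.probe_ids]
    order = np.lexsort((man["pos"].to_numpy(), man["chrom"].to_numpy()))
    man = man.iloc[order]
    m_matrix = m_matrix.iloc[order]
    beta = matrix.beta.iloc[order]

    stats_df = fit_locus_models(m_matrix, samples)
    stats_df = moderate_variances(stats_df)
    usable = stats_df["p_mod"].notna().to_numpy()
    if usable.sum() < len(stats_df):
        log.warning("%d degenerate probes excluded from the HMM", int((~usable).sum()))
    sub = stats_df[usable]
    z = p_to_z(sub["p_mod"].to_numpy(), sub["coef"].to_numpy())
    model, lis = fit_hmm_lis(
        z, man.loc[sub.index, "chrom"].to_numpy(), seed=seed, restarts=hmm_restarts
    )
    calls = adjust_lis(lis, alpha)
    table = stats_df.copy()
    table["chrom"] = man["chrom"].to_numpy()
    table["pos"] = man["pos"].to_numpy()
    table["z"] = np.nan
    table.loc[sub.index, "z"] = z
    for col, default in (("lis", np.nan), ("alis", np.nan), ("called", False)):
        table[col] = default
    table.loc[sub.index, "lis"] = calls["lis"].to_numpy()
    table.loc[sub.index, "alis"] = calls["alis"].to_numpy()
    table.loc[sub.index, "called"] = calls["called"].to_numpy()

    called_ids = table.index[table["called"]]
    table["pearson_r"] = np.nan
    table["direction"] = ""
    if len(called_ids):
        dirs = classify_direction(beta, samples, called_ids, coefs=table["coef"])
        table.loc[dirs.index, "pearson_r"] = dirs["pearson_r"]
        table.loc[dirs.index, "direction"] = dirs["direction"]

    result = DmlResult(
        table=table,
        model=model,
        d0=stats_df.attrs["d0"],
        s0_sq=stats_df.attrs["s0_sq"],
    )
    if snp_table is not None:
        flagged, summary = mqtl_proximity(
            table.reset_index(), snp_table, max_distance=mqtl_distance
        )
        result.table = flagged.set_index("probe_id")
        result.mqtl_summary = summary
    return result
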