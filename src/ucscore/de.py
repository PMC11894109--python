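"""Moderated-t molecular landscape of disease activity.

Per probe set, a two-group comparison of active (endoscopic Mayo subscore
> 1) vs inactive (<= 1) biopsies on the log2 scale, with empirical-Bayes
variance moderation: per-probe residual variances s_g^2 (df d_g) are shrunk
toward a global prior by fitting a scaled inverse-chi-square prior
(hyperparameters d0, s0^2) to the observed variance distribution via
moment matching on log variances.  The posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

yields the moderated statistic t_g = dmean_g / (s~_g * sqrt(1/n1 + 1/n2))
with d0 + d_g degrees of freedom, two-sided p-values, and
Benjamini-Hochberg FDR.  Control samples never enter the test; they only
contribute the linear-scale control geometric mean column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats


# ---------------------------------------------------------------------------
# empirical-Bayes hyperparameter estimation
# ---------------------------------------------------------------------------

def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-10:
            break
    return float(x)


@dataclass
class ModerationParams:
    """Scaled inverse-chi-square prior on per-probe variances."""

    prior_df: float  # d0, may be inf
    prior_var: float  # s0^2


def fit_variance_prior(s2: np.ndarray, df: float) -> ModerationParams:
    """Moment-match the variance prior (d0, s0^2) to observed s_g^2.

    Matching is on log variances: e_g = log s_g^2 - digamma(d/2) + log(d/2)
    estimates log sigma_g^2 without bias; the excess of var(e) over the
    sampling contribution trigamma(d/2) identifies trigamma(d0/2).  When the
    observed variances show no excess dispersion the prior degenerates to a
    point mass (d0 = inf) at the geometric mean of the s_g^2, so that equal
    observed variances shrink to themselves exactly.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return ModerationParams(prior_df=np.inf, prior_var=float(np.mean(s2[ok])) if ok.any() else 1.0)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s20 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        return ModerationParams(prior_df=d0, prior_var=s20)
    return ModerationParams(prior_df=np.inf, prior_var=float(np.exp(np.mean(z))))


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# the model / results pair
# ---------------------------------------------------------------------------

class ModeratedTTest:
    """Two-group moderated-t model over a probe x sample log2 matrix.

    Parameters
    ----------
    matrix
        probes x samples DataFrame of log2 intensities.
    classes
        :class:`~ucscore.data.ClassLabels` defining active/inactive samples.
    control_ids
        Optional control sample ids; used only for the control-mean column.
    annotation
        Optional probe annotation (``gene_symbol`` column) merged into the
        result table.
    """

    def __init__(self, matrix: pd.DataFrame, classes, control_ids=None, annotation=None):
        self.matrix = matrix
        self.classes = classes
        self.control_ids = list(control_ids) if control_ids is not None else []
        self.annotation = annotation
        for group, ids in (("active", classes.active_ids), ("inactive", classes.inactive_ids)):
            if len(ids) < 2:
                raise ValueError(f"need >= 2 samples in the {group} class, got {len(ids)}")
        missing = [s for s in classes.included + self.control_ids if s not in matrix.columns]
        if missing:
            raise ValueError(f"samples absent from matrix: {missing}")

    def fit(self, prior_df: float | None = None, prior_var: float | None = None) -> "DEResults":
        """Fit the per-probe model; optionally force the prior (d0, s0^2)."""
        m = self.matrix
        act = m[self.classes.active_ids].to_numpy(dtype=float)
        ina = m[self.classes.inactive_ids].to_numpy(dtype=float)
        n1, n2 = act.shape[1], ina.shape[1]
        df_resid = n1 + n2 - 2

        mean_a, mean_i = act.mean(axis=1), ina.mean(axis=1)
        delta = mean_a - mean_i
        ss = act.var(axis=1, ddof=0) * n1 + ina.var(axis=1, ddof=0) * n2
        s2 = ss / df_resid

        both = np.concatenate([act, ina], axis=1)
        flat = np.ptp(both, axis=1) == 0.0  # identical across every sample

        if prior_df is not None:
            if prior_var is None:
                prior_var = fit_variance_prior(s2[~flat], df_resid).prior_var
            params = ModerationParams(prior_df=float(prior_df), prior_var=float(prior_var))
        else:
            params = fit_variance_prior(s2[~flat], df_resid)

        d0, s20 = params.prior_df, params.prior_var
        if np.isinf(d0):
            s2_post = np.full_like(s2, s20)
            df_total = np.inf
        elif d0 == 0:
            s2_post = s2.copy()
            df_total = float(df_resid)
        else:
            s2_post = (d0 * s20 + df_resid * s2) / (d0 + df_resid)
            df_total = d0 + df_resid

        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, delta / se, 0.0)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
        t[flat] = 0.0
        p[flat] = 1.0
        p = np.clip(p, 0.0, 1.0)

        table = pd.DataFrame(index=m.index.copy())
        table["mean_active"] = 2.0 ** mean_a
        table["mean_inactive"] = 2.0 ** mean_i
        if self.control_ids:
            table["mean_control"] = 2.0 ** m[self.control_ids].to_numpy(dtype=float).mean(axis=1)
        else:
            table["mean_control"] = np.nan
        table["log2_fold_change"] = delta
        table["t_moderated"] = t
        table["p_unadjusted"] = p
        table["p_fdr"] = benjamini_hochberg(p)
        table["zero_variance"] = flat
        if self.annotation is not None and "gene_symbol" in self.annotation.columns:
            table["gene_symbol"] = self.annotation["gene_symbol"].reindex(table.index).fillna("")
        else:
            table["gene_symbol"] = ""
        return DEResults(table=table, params=params, n_active=n1, n_inactive=n2,
                         df_residual=df_resid)


@dataclass
class DEResults:
    """Fitted moderated-t results: the per-probe table plus hyperparameters."""

    table: pd.DataFrame
    params: ModerationParams
    n_active: int
    n_inactive: int
    df_residual: int

    def top(self, direction: str, k: int, collapse_to_genes: bool = False) -> pd.DataFrame:
        return rank_transcripts(self.table, direction, k, collapse_to_genes)

    def volcano(self, annotation: pd.DataFrame | None = None) -> pd.DataFrame:
        return volcano_table(self.table, annotation)

    def summary(self) -> str:
        t = self.table
        n_sig = int((t["p_fdr"] < 0.05).sum())
        lines = [
            "Moderated t-test: active vs inactive endoscopic Mayo subscore",
            f"  probes tested:        {len(t)}",
            f"  active / inactive n:  {self.n_active} / {self.n_inactive}",
            f"  residual df per probe: {self.df_residual}",
            f"  prior df d0:          {self.params.prior_df:.4g}",
            f"  prior variance s0^2:  {self.params.prior_var:.4g}",
            f"  probes at FDR < 0.05: {n_sig}",
            f"  probes at p < 0.05:   {int((t['p_unadjusted'] < 0.05).sum())}",
        ]
        return "\n".join(lines)


def fit_moderated_t(matrix, classes, control_ids=None, annotation=None,
                    prior_df=None, prior_var=None) -> DEResults:
    """Convenience wrapper around :class:`ModeratedTTest`."""
    model = ModeratedTTest(matrix, classes, control_ids=control_ids, annotation=annotation)
    return model.fit(prior_df=prior_df, prior_var=prior_var)


def rank_transcripts(de_table: pd.DataFrame, direction: str, k: int,
                     collapse_to_genes: bool = False) -> pd.DataFrame:
    """Top-k probes by unadjusted p among increased or decreased transcripts.

    Ties on p break toward larger |log2 fold change|, then lexicographic
    probe id.  With ``collapse_to_genes`` each nonempty gene symbol keeps
    only its best probe ("unique transcripts").
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if direction not in ("increased", "decreased"):
        raise ValueError("direction must be 'increased' or 'decreased'")
    sign = 1 if direction == "increased" else -1
    sub = de_table[sign * de_table["log2_fold_change"] > 0].copy()
    sub["_abs_fc"] = sub["log2_fold_change"].abs()
    sub = (
        sub.rename_axis("probe_id")
        .reset_index()
        .sort_values(["p_unadjusted", "_abs_fc", "probe_id"],
                     ascending=[True, False, True], kind="mergesort")
    )
    if collapse_to_genes and "gene_symbol" in sub.columns:
        named = sub["gene_symbol"].astype(str) != ""
        collapsed = sub[named].drop_duplicates(subset="gene_symbol", keep="first")
        sub = pd.concat([collapsed, sub[~named]]).sort_values(
            ["p_unadjusted", "_abs_fc", "probe_id"],
            ascending=[True, False, True], kind="mergesort",
        )
    return sub.drop(columns="_abs_fc").head(k).set_index("probe_id")


def volcano_table(de_table: pd.DataFrame, annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Volcano coordinates: x = log2 FC, y = -log10 p, flags, FDR-line marker.

    ``fdr_line`` marks the probe with the largest unadjusted p that still
    satisfies FDR < 0.05 (the dashed significance line); the column is all
    False when nothing clears the threshold.
    """
    out = pd.DataFrame(index=de_table.index.copy())
    out["log2_fold_change"] = de_table["log2_fold_change"]
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(de_table["p_unadjusted"])
    if annotation is not None and "flags" in annotation.columns:
        out["flags"] = annotation["flags"].reindex(out.index).fillna("")
    else:
        out["flags"] = ""
    out["fdr_line"] = False
    passing = de_table[de_table["p_fdr"] < 0.05]
    if len(passing) > 0:
        marker = passing["p_unadjusted"].idxmax()
        out.loc[marker, "fdr_line"] = True
    return out
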