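"""Paired tumor-vs-normal differential expression for one-color arrays.

The processing chain mirrors the standard limma-style workflow for paired
one-color microarray data, implemented natively:

1. normexp background correction per array (exponential signal + Gaussian
   noise fitted by maximum likelihood to foreground - background; the
   corrected value is the posterior mean E[S | X = x], strictly positive and
   monotone in x);
2. log2 transform;
3. quantile normalization between arrays;
4. replicate-probe averaging;
5. per-probe paired moderated t statistics with empirical-Bayes variance
   shrinkage, Benjamini-Hochberg adjustment, and selection at
   p_BH < alpha (default 0.01) and fold-change > fc (default 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RawArraySet",
    "DEResult",
    "normexp_fit",
    "normexp_signal",
    "normexp_correct",
    "quantile_normalize",
    "average_replicates",
    "fit_f_dist",
    "paired_moderated_t",
    "bh_adjust",
    "select_de_probes",
    "run_paired_de",
    "paired_log_ratios",
]


@dataclass
class RawArraySet:
    """Probe-level raw intensities for a set of one-color arrays.

    ``foreground``/``background`` are (spots x arrays) DataFrames whose index
    is the probe id (replicate probes appear as repeated index entries) and
    whose columns are array ids. ``samples`` maps each array id to
    (patient_id, tissue) with tissue in {"tumor", "normal"}.
    """

    foreground: pd.DataFrame
    background: pd.DataFrame
    samples: pd.DataFrame  # index: array_id; columns: patient_id, tissue

    def __post_init__(self) -> None:
        if not self.foreground.columns.equals(self.background.columns):
            raise ValueError("foreground/background array columns differ")
        if not self.foreground.index.equals(self.background.index):
            raise ValueError("foreground/background probe rows differ")
        if (self.foreground.to_numpy() <= 0).any() or (self.background.to_numpy() <= 0).any():
            raise ValueError("raw intensities must be strictly positive")
        missing = set(self.foreground.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"arrays without sample annotation: {sorted(missing)}")
        bad = set(self.samples["tissue"]) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"unknown tissue labels: {sorted(bad)}")

    @property
    def patients(self) -> list[str]:
        """Patients with exactly one tumor and one normal array, in first-seen order."""
        seen: list[str] = []
        for pid, grp in self.samples.groupby("patient_id", sort=False):
            tissues = sorted(grp["tissue"])
            if tissues != ["normal", "tumor"]:
                raise ValueError(f"patient {pid} lacks a tumor/normal pair")
            seen.append(str(pid))
        return seen

    def array_for(self, patient_id: str, tissue: str) -> str:
        sel = self.samples[(self.samples["patient_id"] == patient_id) & (self.samples["tissue"] == tissue)]
        return str(sel.index[0])

    def to_tsv(self, intensities_path: str, samples_path: str) -> None:
        long = pd.DataFrame(
            {
                "probe_id": np.repeat(self.foreground.index.to_numpy(), self.foreground.shape[1]),
                "array_id": np.tile(self.foreground.columns.to_numpy(), self.foreground.shape[0]),
                "foreground": self.foreground.to_numpy().ravel(),
                "background": self.background.to_numpy().ravel(),
            }
        )
        long.to_csv(intensities_path, sep="\t", index=False)
        self.samples.rename_axis("array_id").to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, intensities_path: str, samples_path: str) -> "RawArraySet":
        long = pd.read_csv(intensities_path, sep="\t")
        samples = pd.read_csv(samples_path, sep="\t", index_col="array_id")
        arrays = list(dict.fromkeys(long["array_id"]))
        probes_per_array = long.groupby("array_id", sort=False)
        fg = {}
        bg = {}
        index = None
        for aid in arrays:
            sub = probes_per_array.get_group(aid)
            if index is None:
                index = pd.Index(sub["probe_id"])
            fg[aid] = sub["foreground"].to_numpy()
            bg[aid] = sub["background"].to_numpy()
        return cls(pd.DataFrame(fg, index=index), pd.DataFrame(bg, index=index), samples)


@dataclass
class DEResult:
    """Per-probe paired statistics and the retained-probe flag.

    ``table`` columns: log2FC (mean paired log2 difference), t (moderated),
    p, p_bh, retained. ``prior_df``/``prior_var`` are the empirical-Bayes
    hyperparameters actually used.
    """

    table: pd.DataFrame
    alpha: float
    fc: float
    prior_df: float
    prior_var: float

    @property
    def retained_probes(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])

    def summary(self) -> str:
        n = len(self.table)
        k = int(self.table["retained"].sum())
        return (
            f"Paired differential expression: {n} probes, {k} retained "
            f"(p_BH < {self.alpha}, |log2FC| > {np.log2(self.fc):.3g}); "
            f"prior df = {self.prior_df:.3g}, prior var = {self.prior_var:.3g}"
        )

    def to_tsv(self, path: str) -> None:
        self.table.rename_axis("probe_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str, alpha: float = 0.01, fc: float = 2.0) -> "DEResult":
        t = pd.read_csv(path, sep="\t", index_col="probe_id")
        return cls(t, alpha, fc, prior_df=np.nan, prior_var=np.nan)


# ------------------------------------------------------------------ normexp

def _normexp_nll(theta: np.ndarray, x: np.ndarray) -> float:
    mu, log_sigma, log_alpha = theta
    sigma, alpha = np.exp(log_sigma), np.exp(log_alpha)
    z = (x - mu) / sigma - sigma / alpha
    ll = -log_alpha + (mu - x) / alpha + sigma**2 / (2 * alpha**2) + special.log_ndtr(z)
    return -float(ll.sum())


def normexp_fit(x: np.ndarray, max_restarts: int = 3) -> tuple[float, float, float]:
    """Maximum-likelihood fit of the normal+exponential convolution model.

    X = S + B with S ~ Exponential(mean alpha) and B ~ Normal(mu, sigma^2).
    Returns (mu, sigma, alpha). Started from method-of-moments estimates
    (matching mean, variance and skewness); restarted from perturbed starts
    on failure, then raises.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations to fit normexp")
    m, v = float(x.mean()), float(x.var())
    skew = float(stats.skew(x))
    alpha0 = (max(skew, 1e-3) * v**1.5 / 2.0) ** (1 / 3)
    alpha0 = max(alpha0, 1e-6 * (np.sqrt(v) + 1))
    sigma0 = np.sqrt(max(v - alpha0**2, v / 100.0))
    mu0 = m - alpha0
    start = np.array([mu0, np.log(sigma0), np.log(alpha0)])
    rng = np.random.default_rng(0)
    for attempt in range(max_restarts + 1):
        s = start if attempt == 0 else start + rng.normal(0, 0.3, 3)
        res = optimize.minimize(_normexp_nll, s, args=(x,), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
        if res.success and np.all(np.isfinite(res.x)):
            mu, log_sigma, log_alpha = res.x
            return float(mu), float(np.exp(log_sigma)), float(np.exp(log_alpha))
    raise RuntimeError("normexp MLE failed to converge")


def normexp_signal(params: tuple[float, float, float], x: np.ndarray) -> np.ndarray:
    """Posterior mean E[S | X = x] under fitted normexp parameters.

    E[S|X=x] = mu_sx + sigma * phi(mu_sx/sigma) / Phi(mu_sx/sigma) with
    mu_sx = x - mu - sigma^2/alpha; strictly positive and increasing in x.
    """
    mu, sigma, alpha = params
    x = np.asarray(x, dtype=float)
    if sigma < 1e-12:
        return np.maximum(x - mu, 1e-8)
    mu_sx = x - mu - sigma**2 / alpha
    z = mu_sx / sigma
    # sigma * phi(z)/Phi(z), computed in log space for deep negative z
    ratio = np.exp(stats.norm.logpdf(z) - special.log_ndtr(z))
    out = mu_sx + sigma * ratio
    return np.maximum(out, 1e-10)


def normexp_correct(foreground: np.ndarray, background: np.ndarray) -> np.ndarray:
    """normexp-correct one array: fit to foreground - background, return E[S|X]."""
    x = np.asarray(foreground, dtype=float) - np.asarray(background, dtype=float)
    params = normexp_fit(x)
    return normexp_signal(params, x)


# --------------------------------------------------------- normalization

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns: sorted values replaced by across-column means.

    Ties within a column receive the mean of the values they would have been
    assigned. Applying the transform twice equals applying it once.
    """
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values not supported")
    order = np.argsort(x, axis=0, kind="stable")
    sorted_x = np.take_along_axis(x, order, axis=0)
    target = sorted_x.mean(axis=1)
    out = np.empty_like(x)
    for c in range(x.shape[1]):
        col = np.empty(x.shape[0])
        col[order[:, c]] = target
        # ties receive the mean of the target values they would occupy
        _, inv = np.unique(x[:, c], return_inverse=True)
        sums = np.bincount(inv, weights=col)
        counts = np.bincount(inv)
        out[:, c] = (sums / counts)[inv]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def average_replicates(matrix: pd.DataFrame) -> pd.DataFrame:
    """Average replicate probes (rows sharing a probe id), log2 scale assumed.

    Row order of the result follows the first occurrence of each probe id.
    """
    grouped = matrix.groupby(level=0, sort=False).mean()
    return grouped


# --------------------------------------------------- moderated statistics

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes hyperparameters (d0, s0^2) by moment matching on log s^2.

    The sample variances are modeled as s0^2 * F(df, d0) scaled; matching the
    mean and variance of log s^2 against digamma/trigamma moments gives d0
    and s0^2. Returns d0 = inf when the observed spread of log s^2 is no
    larger than expected under a single common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all probe variances are zero")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2))
    if e_var > 0:
        d0 = 2 * _trigamma_inverse(e_var)
        s0 = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        d0 = np.inf
        s0 = float(np.exp(e_mean))
    return d0, s0


def paired_moderated_t(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    prior_df: float | str = "estimate",
) -> pd.DataFrame:
    """Per-probe paired moderated t on aligned (probes x patients) matrices.

    The per-probe variance of the paired differences is shrunk toward the
    empirical-Bayes prior: s_tilde^2 = (d0*s0^2 + df*s^2)/(d0 + df) with
    df = n - 1, and t = mean(d) / (s_tilde/sqrt(n)) referred to a
    t-distribution on df + d0 degrees of freedom. ``prior_df`` may force a
    fixed d0 (0 recovers the ordinary paired t; inf fully pools variances).

    Returns a DataFrame with columns log2FC, t, p and attrs
    ``prior_df``/``prior_var``.
    """
    if not tumor.index.equals(normal.index) or not tumor.columns.equals(normal.columns):
        raise ValueError("tumor and normal matrices must be aligned")
    n = tumor.shape[1]
    if n < 3:
        raise ValueError("need at least 3 patients")
    d = tumor.to_numpy(dtype=float) - normal.to_numpy(dtype=float)
    mean = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    df = n - 1
    if prior_df == "estimate":
        d0, s0 = fit_f_dist(s2, df)
    else:
        d0 = float(prior_df)
        s0 = 0.0 if d0 == 0 else fit_f_dist(s2, df)[1]
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0 + df * s2) / (d0 + df)
        df_total = df + d0
    if np.any(s2_tilde <= 0):
        raise ValueError("zero moderated variance; cannot form t statistics")
    t = mean / np.sqrt(s2_tilde / n)
    p = 2 * stats.t.sf(np.abs(t), df_total if np.isfinite(df_total) else np.inf)
    out = pd.DataFrame({"log2FC": mean, "t": t, "p": p}, index=tumor.index)
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_de_probes(de: pd.DataFrame, alpha: float = 0.01, fc: float = 2.0) -> np.ndarray:
    """Retention rule: p_BH < alpha and |log2FC| > log2(fc), both strict."""
    return (de["p_bh"].to_numpy() < alpha) & (np.abs(de["log2FC"].to_numpy()) > np.log2(fc))


# ------------------------------------------------------------- pipeline

def preprocess(raw: RawArraySet) -> pd.DataFrame:
    """normexp -> log2 -> quantile -> replicate averaging.

    Returns a (unique probes x arrays) log2 expression matrix.
    """
    corrected = {}
    for aid in raw.foreground.columns:
        corrected[aid] = normexp_correct(
            raw.foreground[aid].to_numpy(), raw.background[aid].to_numpy()
        )
    log2m = pd.DataFrame(
        {aid: np.log2(v) for aid, v in corrected.items()}, index=raw.foreground.index
    )
    qn = quantile_normalize(log2m)
    return average_replicates(qn)


def run_paired_de(
    raw: RawArraySet,
    alpha: float = 0.01,
    fc: float = 2.0,
    prior_df: float | str = "estimate",
) -> DEResult:
    """Full paired differential-expression pipeline on a raw array set."""
    expr = preprocess(raw)
    patients = raw.patients
    tumor = expr[[raw.array_for(p, "tumor") for p in patients]]
    normal = expr[[raw.array_for(p, "normal") for p in patients]]
    tumor.columns = patients
    normal.columns = patients
    table = paired_moderated_t(tumor, normal, prior_df=prior_df)
    table["p_bh"] = bh_adjust(table["p"].to_numpy())
    table["retained"] = select_de_probes(table, alpha=alpha, fc=fc)
    return DEResult(table, alpha, fc,
                    prior_df=table.attrs["prior_df"], prior_var=table.attrs["prior_var"])


def paired_log_ratios(raw: RawArraySet, probes: list[str] | None = None) -> pd.DataFrame:
    """Per-patient paired tumor - normal log2 matrix (probes x patients).

    This is the expression representation handed to the module-network
    learner (optionally restricted to ``probes``), before per-probe centering.
    """
    expr = preprocess(raw)
    patients = raw.patients
    tumor = expr[[raw.array_for(p, "tumor") for p in patients]].to_numpy()
    normal = expr[[raw.array_for(p, "normal") for p in patients]].to_numpy()
    out = pd.DataFrame(tumor - normal, index=expr.index, columns=patients)
    if probes is not None:
        out = out.loc[probes]
    return out
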