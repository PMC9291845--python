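"""Stage 2: Bayesian IPD network meta-regression on the baseline risk score.

For patient *i* in study *j* randomized to treatment *t*, with centered
logit risk ``c = logit(R_ij) - mean_j(logit(R_ij))``, the outcome is
Bernoulli with

    logit(p) = u_j + g0 * c                          (baseline arm t = h_j)
    logit(p) = u_j + d_jt + g0 * c + g_jt * c        (t != h_j)

where ``d_jt`` and ``g_jt`` are the study-level contrasts of treatment *t*
versus the study's baseline arm ``h_j``.  Under consistency every contrast
is a difference of basic parameters: ``d_jt = delta_t - delta_h`` and
``g_jt = gamma_t - gamma_h`` with ``delta_ref = gamma_ref = 0``, so the
posterior is parametrized directly in the basic parameters and consistency
holds exactly in every draw.  Study intercepts ``u_j`` are independent
nuisance parameters; priors are vague normals; the common-effect model can
be relaxed to random study-level contrasts with uniform priors on the
between-study standard deviations.

Sampling is adaptive random-walk Metropolis started at the posterior mode
with a Laplace-approximation proposal; convergence is summarized by R-hat
and effective sample size (arviz).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from ._sampler import sample_posterior
from .data import IPDTable, STUDY_COL, TREATMENT_COL
from .risk_model import RiskScoreSet


@dataclass(frozen=True)
class NMRSpec:
    """Settings of the network meta-regression."""

    reference_treatment: str = "placebo"
    effect_model: str = "common"        # "common" | "random"
    interaction_model: str = "common"   # "common" | "random"
    g0_model: str = "common"            # per-study variants reserved
    include_risk_terms: bool = True
    prior_variance: float = 1000.0
    sigma_upper: float = 5.0
    chains: int = 2
    iterations: int = 10_000
    burn_in: int = 1_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_variance <= 0:
            raise ValueError("prior_variance must be positive")
        if self.effect_model not in ("common", "random"):
            raise ValueError("effect_model must be 'common' or 'random'")
        if self.interaction_model not in ("common", "random"):
            raise ValueError("interaction_model must be 'common' or 'random'")
        if self.g0_model != "common":
            raise ValueError("only the common g0 model is implemented")


def reduce_to_nma(spec: NMRSpec) -> NMRSpec:
    """Disable the risk-score terms, leaving a plain network meta-analysis."""
    return dataclasses.replace(spec, include_risk_terms=False)


def linear_predictor(
    u_j: float,
    delta: float,
    gamma0: float,
    gamma_t: float,
    centered_logit_risk: float,
    is_baseline_arm: bool,
) -> float:
    """Mean-structure arithmetic for one patient.

    ``delta`` and ``gamma_t`` are the study-level contrasts of the
    patient's arm versus the study's baseline arm; both are ignored on the
    baseline arm.
    """
    c = centered_logit_risk
    if is_baseline_arm:
        return u_j + gamma0 * c
    return u_j + delta + gamma0 * c + gamma_t * c


def study_baseline_arm(arms: list[str], reference: str) -> str:
    """The study's baseline arm: overall reference if present, else first alphabetical."""
    return reference if reference in arms else sorted(arms)[0]


@dataclass
class NMRPosterior:
    """Posterior draws of the network meta-regression parameters."""

    param_names: list[str]
    draws: np.ndarray  # (chains, draws_per_chain, dim)
    spec: NMRSpec
    treatments: list[str]  # reference first
    studies: list[str]
    accept_rates: np.ndarray | None = None
    _summary_cache: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.param_names):
            raise ValueError("draws must have shape (chains, n, dim)")

    # -- accessors -------------------------------------------------------
    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def flat(self, name: str) -> np.ndarray:
        i = self.param_names.index(name)
        return self.draws[:, :, i].reshape(-1)

    def delta(self, treatment: str) -> np.ndarray:
        """Per-draw log-OR of ``treatment`` vs the overall reference."""
        if treatment == self.spec.reference_treatment:
            return np.zeros(self.n_draws)
        return self.flat(f"delta[{treatment}]")

    def gamma(self, treatment: str) -> np.ndarray:
        """Per-draw effect modification of ``treatment`` vs the reference."""
        if treatment == self.spec.reference_treatment:
            return np.zeros(self.n_draws)
        if not self.spec.include_risk_terms:
            return np.zeros(self.n_draws)
        return self.flat(f"gamma[{treatment}]")

    def gamma0(self) -> np.ndarray:
        if not self.spec.include_risk_terms:
            return np.zeros(self.n_draws)
        return self.flat("gamma0")

    def contrast(self, h: str, t: str) -> np.ndarray:
        """Consistency contrast D_ht = delta_t - delta_h, per draw (exact)."""
        return self.delta(t) - self.delta(h)

    def interaction_contrast(self, h: str, t: str) -> np.ndarray:
        """G_ht = gamma_t - gamma_h, per draw (exact)."""
        return self.gamma(t) - self.gamma(h)

    # -- diagnostics and I/O ---------------------------------------------
    def to_inference_data(self) -> az.InferenceData:
        return az.from_dict({n: self.draws[:, :, i] for i, n in enumerate(self.param_names)})

    def summary(self) -> pd.DataFrame:
        if self._summary_cache is None:
            idata = self.to_inference_data()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s = az.summary(idata, hdi_prob=0.95, kind="all")
                quants = {
                    name: np.percentile(self.flat(name), [2.5, 50.0, 97.5])
                    for name in self.param_names
                }
            s = s.loc[self.param_names]
            s["q2.5"] = [quants[n][0] for n in self.param_names]
            s["median"] = [quants[n][1] for n in self.param_names]
            s["q97.5"] = [quants[n][2] for n in self.param_names]
            self._summary_cache = s
        return self._summary_cache

    def credible_interval(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        lo, hi = np.percentile(self.flat(name), [(1 - prob) / 2 * 100, (1 + prob) / 2 * 100])
        return float(lo), float(hi)

    def max_rhat(self) -> float:
        return float(self.summary()["r_hat"].max())

    def to_csv(self, path: str | Path) -> None:
        flat = self.draws.reshape(-1, len(self.param_names))
        pd.DataFrame(flat, columns=self.param_names).to_csv(path, index=False)

    def summary_json(self, path: str | Path) -> None:
        s = self.summary()
        out = {
            name: {
                "mean": float(s.loc[name, "mean"]),
                "sd": float(s.loc[name, "sd"]),
                "q2.5": float(s.loc[name, "q2.5"]),
                "median": float(s.loc[name, "median"]),
                "q97.5": float(s.loc[name, "q97.5"]),
                "r_hat": float(s.loc[name, "r_hat"]),
                "ess_bulk": float(s.loc[name, "ess_bulk"]),
            }
            for name in self.param_names
        }
        Path(path).write_text(json.dumps(out, indent=2))


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

def check_connected(table: IPDTable, reference: str) -> None:
    """Every treatment must be reachable from the reference through studies."""
    G = nx.Graph()
    G.add_nodes_from(table.treatments)
    for _, grp in table.data.groupby(STUDY_COL, observed=True):
        arms = sorted(grp[TREATMENT_COL].astype(str).unique())
        if len(arms) < 2:
            raise ValueError(f"study with a single arm cannot inform contrasts: {arms}")
        G.add_edges_from((arms[0], a) for a in arms[1:])
    if reference not in G:
        raise ValueError(f"reference treatment {reference!r} absent from the data")
    reachable = nx.node_connected_component(G, reference)
    missing = sorted(set(table.treatments) - reachable)
    if missing:
        raise ValueError(f"network disconnected: {missing} unreachable from {reference!r}")


def _build_design(
    table: IPDTable, scores: RiskScoreSet, spec: NMRSpec
) -> tuple[np.ndarray, np.ndarray, list[str], list[str], list[str], dict]:
    """Design matrix mapping the basic-parameter vector to patient logits."""
    df = table.data
    if not df.index.equals(scores.logit_risk.index):
        raise ValueError("scores do not cover the table's patients (index mismatch)")
    y = df["outcome"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("outcomes contain missing values")
    c = scores.centered().to_numpy(dtype=float)

    studies = sorted(df[STUDY_COL].astype(str).unique())
    ref = spec.reference_treatment
    treatments = [ref] + [t for t in sorted(df[TREATMENT_COL].astype(str).unique()) if t != ref]
    nonref = treatments[1:]

    names: list[str] = [f"u[{s}]" for s in studies]
    names += [f"delta[{t}]" for t in nonref]
    if spec.include_risk_terms:
        names += ["gamma0"] + [f"gamma[{t}]" for t in nonref]

    # random-effect deviations: one per (study, non-baseline arm) contrast
    re_d_keys: list[tuple[str, str]] = []
    re_g_keys: list[tuple[str, str]] = []
    study_arms = {s: sorted(g[TREATMENT_COL].astype(str).unique())
                  for s, g in df.groupby(STUDY_COL, observed=True)}
    baselines = {s: study_baseline_arm(arms, ref) for s, arms in study_arms.items()}
    if spec.effect_model == "random":
        re_d_keys = [(s, t) for s in studies for t in study_arms[s] if t != baselines[s]]
        names += [f"eps_d[{s}:{t}]" for s, t in re_d_keys]
    if spec.include_risk_terms and spec.interaction_model == "random":
        re_g_keys = [(s, t) for s in studies for t in study_arms[s] if t != baselines[s]]
        names += [f"eps_g[{s}:{t}]" for s, t in re_g_keys]
    n_sigma = int(bool(re_d_keys)) + int(bool(re_g_keys))
    sigma_names = []
    if re_d_keys:
        sigma_names.append("sigma_D")
    if re_g_keys:
        sigma_names.append("sigma_G")
    names += sigma_names

    col = {name: i for i, name in enumerate(names)}
    n = len(df)
    X = np.zeros((n, len(names)))
    study_arr = df[STUDY_COL].astype(str).to_numpy()
    trt_arr = df[TREATMENT_COL].astype(str).to_numpy()

    for s in studies:
        X[study_arr == s, col[f"u[{s}]"]] = 1.0
    if spec.include_risk_terms:
        X[:, col["gamma0"]] = c
    for s in studies:
        h = baselines[s]
        in_s = study_arr == s
        for t in study_arms[s]:
            if t == h:
                continue
            m = in_s & (trt_arr == t)
            if t != ref:
                X[m, col[f"delta[{t}]"]] += 1.0
            if h != ref:
                X[m, col[f"delta[{h}]"]] -= 1.0
            if spec.include_risk_terms:
                if t != ref:
                    X[m, col[f"gamma[{t}]"]] += c[m]
                if h != ref:
                    X[m, col[f"gamma[{h}]"]] -= c[m]
            if (s, t) in re_d_keys:
                X[m, col[f"eps_d[{s}:{t}]"]] = 1.0
            if (s, t) in re_g_keys:
                X[m, col[f"eps_g[{s}:{t}]"]] = c[m]

    meta = {
        "baselines": baselines,
        "re_d": [col[f"eps_d[{s}:{t}]"] for s, t in re_d_keys],
        "re_g": [col[f"eps_g[{s}:{t}]"] for s, t in re_g_keys],
        "sigma": [col[nm] for nm in sigma_names],
        "n_fixed": len(names) - len(re_d_keys) - len(re_g_keys) - n_sigma,
    }
    return X, y, names, studies, treatments, meta


def fit_nmr(table: IPDTable, scores: RiskScoreSet, spec: NMRSpec) -> NMRPosterior:
    """Sample the posterior of the network meta-regression."""
    check_connected(table, spec.reference_treatment)
    X, y, names, studies, treatments, meta = _build_design(table, scores, spec)
    n_fixed = meta["n_fixed"]
    re_d, re_g, sig_idx = meta["re_d"], meta["re_g"], meta["sigma"]
    has_sigma = bool(sig_idx)
    tau = 1.0 / spec.prior_variance
    sigma_upper = spec.sigma_upper
    Xlik = X[:, : len(names) - len(sig_idx)] if has_sigma else X

    sig_d_pos = names.index("sigma_D") if "sigma_D" in names else None
    sig_g_pos = names.index("sigma_G") if "sigma_G" in names else None

    def log_post(theta: np.ndarray) -> float:
        if has_sigma:
            sig = theta[sig_idx]
            if np.any(sig <= 0) or np.any(sig >= sigma_upper):
                return -np.inf
        eta = Xlik @ theta[: Xlik.shape[1]]
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        lp = ll - 0.5 * tau * float(theta[:n_fixed] @ theta[:n_fixed])
        if re_d:
            s = theta[sig_d_pos]
            dev = theta[re_d]
            lp += -len(dev) * np.log(s) - 0.5 * float(dev @ dev) / s**2
        if re_g:
            s = theta[sig_g_pos]
            dev = theta[re_g]
            lp += -len(dev) * np.log(s) - 0.5 * float(dev @ dev) / s**2
        return lp

    x0, cov0 = _laplace_start(Xlik, y, n_fixed, len(names), sig_idx, tau, table, spec, names, studies)
    draws, accept = sample_posterior(
        log_post, x0, cov0,
        chains=spec.chains, iterations=spec.iterations,
        burn_in=spec.burn_in, thin=spec.thin, seed=spec.seed,
    )
    post = NMRPosterior(
        param_names=names, draws=draws, spec=spec,
        treatments=treatments, studies=studies, accept_rates=accept,
    )
    rhat = post.max_rhat()
    if rhat > 1.05:
        warnings.warn(f"possible non-convergence: max R-hat = {rhat:.3f}")
    return post


def _laplace_start(
    Xlik: np.ndarray, y: np.ndarray, n_fixed: int, dim: int,
    sig_idx: list[int], tau: float,
    table: IPDTable, spec: NMRSpec, names: list[str], studies: list[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and Laplace covariance used to seed the sampler.

    Random-effect deviations are profiled at zero with a unit-variance
    working prior; between-study SDs start at 0.5 with a modest proposal
    scale.  Study intercepts start at the observed baseline-arm log-odds.
    """
    p = Xlik.shape[1]
    prior_prec = np.full(p, tau)
    prior_prec[n_fixed:] = 1.0  # working prior for deviations during mode finding
    theta = np.zeros(p)
    for j, s in enumerate(studies):
        grp = table.data[table.data[STUDY_COL].astype(str) == s]
        arms = sorted(grp[TREATMENT_COL].astype(str).unique())
        h = study_baseline_arm(arms, spec.reference_treatment)
        yb = grp.loc[grp[TREATMENT_COL].astype(str) == h, "outcome"].to_numpy(dtype=float)
        e = yb.sum() + 0.5
        theta[names.index(f"u[{s}]")] = np.log(e / (len(yb) - yb.sum() + 0.5))

    for _ in range(50):
        eta = Xlik @ theta
        mu = expit(eta)
        grad = Xlik.T @ (y - mu) - prior_prec * theta
        W = mu * (1 - mu)
        H = Xlik.T @ (Xlik * W[:, None]) + np.diag(prior_prec)
        step = np.linalg.solve(H, grad)
        theta = theta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    cov = np.linalg.inv(H)

    x0 = np.zeros(dim)
    x0[:p] = theta
    full_cov = np.zeros((dim, dim))
    full_cov[:p, :p] = cov
    for i in sig_idx:
        x0[i] = 0.5
        full_cov[i, i] = 0.01
    return x0, full_cov
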