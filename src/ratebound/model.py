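"""Maximum-likelihood dual-rate codon models: discrete gamma and GDD.

`DualRateCodonModel` binds one alignment/tree pair to the MG94-style codon
model; `fit` maximizes the pruning likelihood over the rate-distribution
parameters and returns a `DualRateResults` carrying the fitted
distributions, their CVs (computed from the discretized distributions
themselves, which is what the sqrt(K-1) bound constrains), bound-saturation
flags, and convergence diagnostics.

Two rate families are supported:

* ``discrete_gamma`` — both classes are unit-mean gammas discretized into K
  equiprobable interval-mean categories; one shape parameter per class.
* ``gdd`` — general discrete distribution: both the K rates and their K
  weights are free (2K - 1 effective parameters per class after the
  unit-mean and simplex constraints).

Identifiability: both rate distributions are constrained to unit mean;
input branch lengths carry the synonymous time scale through a single
fitted branch-scale factor, and ``nonsyn_scale`` carries the mean
omega-like nonsynonymous/synonymous ratio.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .data import CodonAlignment, PhyloTree
from .genetics import CodonModelParams
from .likelihood import DualRateModel, PruningEngine
from .ratedist import (
    DiscreteRateDistribution,
    GammaSpec,
    cv_upper_bound,
    discretize_gamma,
    is_at_bound,
)

__all__ = ["DualRateCodonModel", "DualRateResults", "SiteRatePosterior",
           "fit_discrete_gamma", "fit_gdd", "posterior_site_rates"]

LOG_ALPHA_BOUNDS = (math.log(1e-3), math.log(100.0))
LOG_OMEGA_BOUNDS = (math.log(1e-4), math.log(100.0))
LOG_BRANCH_BOUNDS = (math.log(1e-3), math.log(1e3))
LOG_KAPPA_BOUNDS = (math.log(0.05), math.log(50.0))
GDD_RATE_BOUNDS = (-14.0, 14.0)
GDD_WEIGHT_BOUNDS = (-16.0, 16.0)
DEGENERATE_WEIGHT = 1e-6


def _softmax0(z: np.ndarray) -> np.ndarray:
    full = np.concatenate(([0.0], z))
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


def _gdd_from_params(y: np.ndarray, z: np.ndarray) -> DiscreteRateDistribution:
    """Rates from log-offsets (first fixed at 0), weights from logits
    (first fixed at 0); rates renormalized to unit weighted mean."""
    g = np.exp(np.concatenate(([0.0], y)))
    w = _softmax0(z)
    r = g / float(w @ g)
    return DiscreteRateDistribution.from_unsorted(r, w)


def _gdd_params_from_dist(dist: DiscreteRateDistribution):
    r = np.clip(np.asarray(dist.rates), 1e-6, None)
    y = np.clip(np.log(r[1:] / r[0]), *GDD_RATE_BOUNDS)
    w = np.asarray(dist.weights)
    z = np.clip(np.log(w[1:] / w[0]), *GDD_WEIGHT_BOUNDS)
    return y, z


class DualRateCodonModel:
    """Dual-rate codon model bound to one alignment and tree.

    Parameters
    ----------
    alignment, tree
        The data.  Tree leaf labels must match alignment taxa; unrooted
        trees are accepted (the reversible likelihood is root-invariant).
    kappa : float
        Initial transition/transversion ratio; fitted unless
        ``estimate_kappa=False``.
    frequencies : {"f3x4", "flat"}
        Equilibrium codon frequencies: empirical F3x4 from the alignment,
        or flat over the 61 sense codons.
    """

    def __init__(self, alignment: CodonAlignment, tree: PhyloTree,
                 kappa: float = 2.0, frequencies: str = "f3x4",
                 estimate_kappa: bool = True):
        self.alignment = alignment
        self.tree = tree
        self.kappa0 = float(kappa)
        self.estimate_kappa = bool(estimate_kappa)
        if frequencies == "f3x4":
            counts = alignment.position_nucleotide_counts() + 1.0
            self._pos_freqs = counts / counts.sum(axis=1, keepdims=True)
        elif frequencies == "flat":
            self._pos_freqs = np.full((3, 4), 0.25)
        else:
            raise ValueError(f"unknown frequencies choice {frequencies!r}")
        self.frequencies = frequencies
        self.engine = PruningEngine(alignment, tree)
        self._params_cache: dict = {}

    @classmethod
    def from_files(cls, fasta_path, newick_path, **kwargs) -> "DualRateCodonModel":
        return cls(CodonAlignment.read_fasta(fasta_path),
                   PhyloTree.read_newick(newick_path), **kwargs)

    def codon_params(self, kappa: float) -> CodonModelParams:
        key = round(float(kappa), 12)
        if key not in self._params_cache:
            if len(self._params_cache) > 256:
                self._params_cache.clear()
            self._params_cache[key] = CodonModelParams(
                kappa=key, position_freqs=self._pos_freqs
            )
        return self._params_cache[key]

    def loglike(self, syn_dist: DiscreteRateDistribution,
                nonsyn_dist: DiscreteRateDistribution,
                nonsyn_scale: float, branch_scale: float,
                kappa: float | None = None) -> float:
        """Log-likelihood at explicit parameter values."""
        model = DualRateModel(
            params=self.codon_params(self.kappa0 if kappa is None else kappa),
            syn_dist=syn_dist, nonsyn_dist=nonsyn_dist,
            nonsyn_scale=nonsyn_scale,
        )
        return self.engine.log_likelihood(model, branch_scale)

    # ---------------------------------------------------------------- fit

    def fit(self, method: str = "discrete_gamma", k_syn: int = 3,
            k_nonsyn: int | None = None, start=None, seed: int = 0,
            n_restarts: int | None = None, maxiter: int | None = None,
            bound_tolerance: float = 1e-3) -> "DualRateResults":
        """Fit by maximum likelihood.

        ``method`` is ``"discrete_gamma"`` or ``"gdd"``.  ``start`` may be a
        previous `DualRateResults` (warm start, e.g. across K) or a dict of
        parameter values.  ``seed`` drives the GDD random restarts.
        """
        if k_nonsyn is None:
            k_nonsyn = k_syn
        if k_syn < 2 or k_nonsyn < 2:
            raise ValueError("fitting requires K >= 2 for both rate classes")
        if method == "discrete_gamma":
            return self._fit_discrete_gamma(k_syn, k_nonsyn, start, maxiter,
                                            bound_tolerance)
        if method == "gdd":
            return self._fit_gdd(k_syn, k_nonsyn, start, seed,
                                 3 if n_restarts is None else n_restarts,
                                 maxiter, bound_tolerance)
        raise ValueError(f"unknown method {method!r}")

    def _dg_theta0(self, start):
        if isinstance(start, DualRateResults):
            p = start.params
            theta = [math.log(p.get("alpha_syn", 0.5)),
                     math.log(p.get("alpha_nonsyn", 0.5)),
                     math.log(p["nonsyn_scale"]), math.log(p["branch_scale"])]
            kappa = p.get("kappa", self.kappa0)
        elif isinstance(start, dict):
            theta = [math.log(start.get("alpha_syn", 0.5)),
                     math.log(start.get("alpha_nonsyn", 0.5)),
                     math.log(start.get("nonsyn_scale", 0.3)),
                     math.log(start.get("branch_scale", 1.0))]
            kappa = start.get("kappa", self.kappa0)
        else:
            theta = [math.log(0.5), math.log(0.5), math.log(0.3), 0.0]
            kappa = self.kappa0
        if self.estimate_kappa:
            theta.append(math.log(kappa))
        return np.asarray(theta)

    def _fit_discrete_gamma(self, k_syn, k_nonsyn, start, maxiter, tol):
        bounds = [LOG_ALPHA_BOUNDS, LOG_ALPHA_BOUNDS,
                  LOG_OMEGA_BOUNDS, LOG_BRANCH_BOUNDS]
        if self.estimate_kappa:
            bounds.append(LOG_KAPPA_BOUNDS)

        def unpack(theta):
            a_s, a_n, w, b = np.exp(theta[:4])
            kappa = math.exp(theta[4]) if self.estimate_kappa else self.kappa0
            syn = discretize_gamma(GammaSpec(a_s), k_syn)
            nonsyn = discretize_gamma(GammaSpec(a_n), k_nonsyn)
            return syn, nonsyn, w, b, kappa, {"alpha_syn": a_s, "alpha_nonsyn": a_n}

        res = self._maximize(unpack, self._dg_theta0(start), bounds,
                             maxiter or 300, ftol=1e-9)
        # the surface can hold two basins per class: a bound-saturated one
        # (alpha in the flat region near the floor, CV pinned at sqrt(K-1))
        # and an interior one.  Probe the opposite regime of each class so
        # the saturation flags reflect the global optimum, skipping probes
        # that cannot matter (fitted CV far below the ceiling).
        a_s, a_n = math.exp(res.x[0]), math.exp(res.x[1])
        flip = {}
        for name, a, k in (("alpha_syn", a_s, k_syn),
                           ("alpha_nonsyn", a_n, k_nonsyn)):
            cv = discretize_gamma(GammaSpec(a), k).cv
            ceiling = cv_upper_bound(k)
            if cv >= (1 - tol) * ceiling:
                flip[name] = 0.25          # saturated: probe the interior
            elif cv >= 0.8 * ceiling:
                flip[name] = 0.02          # near the ceiling: probe saturation
            else:
                flip[name] = a             # ceiling not active: no probe
        restarts = 1
        if not (np.isclose(flip["alpha_syn"], a_s)
                and np.isclose(flip["alpha_nonsyn"], a_n)):
            flip.update(nonsyn_scale=math.exp(res.x[2]),
                        branch_scale=math.exp(res.x[3]))
            if self.estimate_kappa:
                flip["kappa"] = math.exp(res.x[4])
            res2 = self._maximize(unpack, self._dg_theta0(flip), bounds,
                                  maxiter or 120, ftol=1e-9)
            restarts = 2
            if -res2.fun > -res.fun:
                res = res2
        return self._package("discrete_gamma", k_syn, k_nonsyn, unpack, res,
                             tol, restarts=restarts)

    def _gdd_theta0_list(self, k_syn, k_nonsyn, start, seed, n_restarts):
        """Initial points: an informed start from a discrete-gamma (pre)fit
        plus seeded random perturbations."""
        if isinstance(start, DualRateResults) and start.method == "gdd" \
                and start.k_syn == k_syn and start.k_nonsyn == k_nonsyn:
            informed = self._gdd_pack(start.syn_dist, start.nonsyn_dist,
                                      start.params["nonsyn_scale"],
                                      start.params["branch_scale"],
                                      start.params.get("kappa", self.kappa0))
        else:
            dg = start
            if not (isinstance(dg, DualRateResults)
                    and dg.k_syn == k_syn and dg.k_nonsyn == k_nonsyn):
                dg = self._fit_discrete_gamma(k_syn, k_nonsyn, dg, 150, 1e-3)
            informed = self._gdd_pack(dg.syn_dist, dg.nonsyn_dist,
                                      dg.params["nonsyn_scale"],
                                      dg.params["branch_scale"],
                                      dg.params.get("kappa", self.kappa0))
        starts = [informed]
        rng = np.random.default_rng(seed)
        for _ in range(max(n_restarts - 1, 0)):
            theta = informed.copy()
            theta[: 2 * (k_syn - 1) + 2 * (k_nonsyn - 1)] = np.concatenate([
                np.clip(rng.normal(1.5, 2.0, k_syn - 1), *GDD_RATE_BOUNDS),
                rng.normal(0.0, 1.0, k_syn - 1),
                np.clip(rng.normal(1.5, 2.0, k_nonsyn - 1), *GDD_RATE_BOUNDS),
                rng.normal(0.0, 1.0, k_nonsyn - 1),
            ])
            starts.append(theta)
        return starts

    def _gdd_pack(self, syn, nonsyn, nonsyn_scale, branch_scale, kappa):
        ys, zs = _gdd_params_from_dist(syn)
        yn, zn = _gdd_params_from_dist(nonsyn)
        theta = np.concatenate([ys, zs, yn, zn,
                                [math.log(nonsyn_scale), math.log(branch_scale)]])
        if self.estimate_kappa:
            theta = np.concatenate([theta, [math.log(kappa)]])
        return theta

    def _fit_gdd(self, k_syn, k_nonsyn, start, seed, n_restarts, maxiter, tol):
        ks1, kn1 = k_syn - 1, k_nonsyn - 1
        bounds = ([GDD_RATE_BOUNDS] * ks1 + [GDD_WEIGHT_BOUNDS] * ks1
                  + [GDD_RATE_BOUNDS] * kn1 + [GDD_WEIGHT_BOUNDS] * kn1
                  + [LOG_OMEGA_BOUNDS, LOG_BRANCH_BOUNDS])
        if self.estimate_kappa:
            bounds.append(LOG_KAPPA_BOUNDS)

        def unpack(theta):
            i = 0
            ys = theta[i:i + ks1]; i += ks1
            zs = theta[i:i + ks1]; i += ks1
            yn = theta[i:i + kn1]; i += kn1
            zn = theta[i:i + kn1]; i += kn1
            w, b = np.exp(theta[i:i + 2]); i += 2
            kappa = math.exp(theta[i]) if self.estimate_kappa else self.kappa0
            return (_gdd_from_params(ys, zs), _gdd_from_params(yn, zn),
                    w, b, kappa, {})

        # multimodal surface: run the informed start to convergence, probe
        # the random restarts with a capped budget, and polish a probe only
        # when it lands near or above the informed optimum
        starts = self._gdd_theta0_list(k_syn, k_nonsyn, start, seed, n_restarts)
        full_iter = maxiter or 100

        def run_full(theta0):
            res = self._maximize(unpack, theta0, bounds, full_iter)
            if not res.success:
                # budget exhausted on a flat ridge: declare a plateau if a
                # short continuation cannot improve the fit meaningfully
                cont = self._maximize(unpack, res.x, bounds, 25)
                gain = -cont.fun - (-res.fun)
                if gain < 0.05:
                    cont.success = True
                    cont.message = (f"plateau: continuation improved by "
                                    f"{gain:.2e} logL")
                if -cont.fun > -res.fun:
                    res = cont
                res.success = cont.success
                res.message = cont.message
            return res

        best = run_full(starts[0])
        all_status = [bool(best.success)]
        best_probe = None
        for theta0 in starts[1:]:
            probe = self._maximize(unpack, theta0, bounds, 8)
            if best_probe is None or -probe.fun > -best_probe.fun:
                best_probe = probe
        if best_probe is not None and -best_probe.fun > -best.fun - 2.0:
            polished = run_full(best_probe.x)
            all_status.append(bool(polished.success))
            if -polished.fun > -best.fun:
                best = polished
        out = self._package("gdd", k_syn, k_nonsyn, unpack, best, tol,
                            restarts=len(starts))
        out.diagnostics["restart_successes"] = all_status
        out.diagnostics["converged"] = any(all_status)
        return out

    def _maximize(self, unpack, theta0, bounds, maxiter, ftol=1e-7):
        def nll(theta):
            try:
                syn, nonsyn, w, b, kappa, _ = unpack(theta)
                return -self.loglike(syn, nonsyn, w, b, kappa)
            except (ValueError, RuntimeError, OverflowError):
                return 1e12
        theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
        # stopping rules sized for the quantities reported (CVs to ~1e-3);
        # the looser default ftol matters on the flat GDD ridges, where
        # demanding machine-level f-improvements burns the whole eval budget
        return minimize(nll, theta0, method="L-BFGS-B", bounds=bounds,
                        options={"maxiter": maxiter, "maxfun": 6 * maxiter,
                                 "ftol": ftol, "gtol": 2e-2, "eps": 3e-5})

    def _package(self, method, k_syn, k_nonsyn, unpack, res, tol, restarts):
        syn, nonsyn, w, b, kappa, extra = unpack(res.x)
        params = {"nonsyn_scale": float(w), "branch_scale": float(b),
                  "kappa": float(kappa), **{k: float(v) for k, v in extra.items()}}
        diagnostics = {
            "converged": bool(res.success),
            "status": str(res.message),
            "iterations": int(res.nit),
            "function_evaluations": int(res.nfev),
            "restarts": restarts,
            "warnings": [],
        }
        if method == "discrete_gamma":
            for name in ("alpha_syn", "alpha_nonsyn"):
                a = params[name]
                for edge, side in ((math.exp(LOG_ALPHA_BOUNDS[0]), "lower"),
                                   (math.exp(LOG_ALPHA_BOUNDS[1]), "upper")):
                    if abs(math.log(a) - math.log(edge)) < 1e-9:
                        diagnostics["warnings"].append(
                            f"{name} at {side} search bound ({edge:g})")
        for label, dist in (("syn", syn), ("nonsyn", nonsyn)):
            tiny = [i for i, wt in enumerate(dist.weights) if wt < DEGENERATE_WEIGHT]
            if tiny:
                diagnostics["warnings"].append(
                    f"degenerate {label} weight(s) at categories {tiny}; "
                    "pruned in effective distribution")
        return DualRateResults(
            model=self, method=method, k_syn=k_syn, k_nonsyn=k_nonsyn,
            syn_dist=syn, nonsyn_dist=nonsyn, llf=float(-res.fun),
            params=params, diagnostics=diagnostics,
            bound_tolerance=tol,
        )


class DualRateResults:
    """Fitted dual-rate codon model: estimates, CVs, saturation flags."""

    def __init__(self, model, method, k_syn, k_nonsyn, syn_dist, nonsyn_dist,
                 llf, params, diagnostics, bound_tolerance=1e-3):
        self.model = model
        self.method = method
        self.k_syn = k_syn
        self.k_nonsyn = k_nonsyn
        self.syn_dist = syn_dist
        self.nonsyn_dist = nonsyn_dist
        self.llf = llf
        self.params = params
        self.diagnostics = diagnostics
        self.bound_tolerance = bound_tolerance

    # CVs come from the fitted discrete distributions themselves
    @property
    def cv_syn(self) -> float:
        return self.syn_dist.cv

    @property
    def cv_nonsyn(self) -> float:
        return self.nonsyn_dist.cv

    @property
    def at_bound_syn(self):
        """Saturation flag; defined only for equiprobable (discrete-gamma)
        fits, ``None`` for GDD."""
        if self.method != "discrete_gamma":
            return None
        return is_at_bound(self.syn_dist, self.bound_tolerance)

    @property
    def at_bound_nonsyn(self):
        if self.method != "discrete_gamma":
            return None
        return is_at_bound(self.nonsyn_dist, self.bound_tolerance)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def effective_distributions(self):
        """Fitted distributions with degenerate (< 1e-6) weights pruned."""
        out = []
        for dist in (self.syn_dist, self.nonsyn_dist):
            keep = [(r, w) for r, w in zip(dist.rates, dist.weights)
                    if w >= DEGENERATE_WEIGHT]
            rates, weights = zip(*keep)
            out.append(DiscreteRateDistribution.from_unsorted(rates, weights))
        return tuple(out)

    def posterior_site_rates(self) -> "SiteRatePosterior":
        return posterior_site_rates(self.model.alignment, self.model.tree,
                                    self, _model=self.model)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "k_syn": self.k_syn, "k_nonsyn": self.k_nonsyn,
            "log_likelihood": self.llf,
            "params": self.params,
            "syn_dist": self.syn_dist.to_json_dict(),
            "nonsyn_dist": self.nonsyn_dist.to_json_dict(),
            "cv_syn": self.cv_syn, "cv_nonsyn": self.cv_nonsyn,
            "at_bound_syn": self.at_bound_syn,
            "at_bound_nonsyn": self.at_bound_nonsyn,
            "bound_tolerance": self.bound_tolerance,
            "diagnostics": self.diagnostics,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        lines = [
            "Dual-rate codon model fit",
            "=" * 58,
            f"method: {self.method}    K_syn: {self.k_syn}    "
            f"K_nonsyn: {self.k_nonsyn}",
            f"log-likelihood: {self.llf:.4f}    converged: {self.converged}",
            f"kappa: {self.params['kappa']:.4f}    "
            f"nonsyn scale (omega-like): {self.params['nonsyn_scale']:.4f}    "
            f"branch scale: {self.params['branch_scale']:.4f}",
        ]
        if self.method == "discrete_gamma":
            lines.append(f"alpha_syn: {self.params['alpha_syn']:.5g}    "
                         f"alpha_nonsyn: {self.params['alpha_nonsyn']:.5g}")
        for label, dist, cv, bound, flag in (
            ("synonymous", self.syn_dist, self.cv_syn,
             cv_upper_bound(self.k_syn), self.at_bound_syn),
            ("nonsynonymous", self.nonsyn_dist, self.cv_nonsyn,
             cv_upper_bound(self.k_nonsyn), self.at_bound_nonsyn),
        ):
            lines.append("-" * 58)
            lines.append(f"{label} rate distribution (unit mean)")
            lines.append("  rates:   " + "  ".join(f"{r:8.4f}" for r in dist.rates))
            lines.append("  weights: " + "  ".join(f"{w:8.4f}" for w in dist.weights))
            at = {True: "AT BOUND", False: "below bound", None: "n/a (GDD)"}[flag]
            lines.append(f"  CV: {cv:.4f}   sqrt(K-1) ceiling: {bound:.4f}   {at}")
        if self.diagnostics.get("warnings"):
            lines.append("-" * 58)
            for w in self.diagnostics["warnings"]:
                lines.append(f"warning: {w}")
        return "\n".join(lines)


@dataclass(frozen=True)
class SiteRatePosterior:
    """Empirical-Bayes posterior over joint rate categories at each site."""

    posterior: np.ndarray          # (n_sites, ncat), rows sum to 1
    joint_syn_rates: np.ndarray    # (ncat,)
    joint_nonsyn_rates: np.ndarray
    prior_weights: np.ndarray

    @property
    def mean_syn_rate(self) -> np.ndarray:
        return self.posterior @ self.joint_syn_rates

    @property
    def mean_nonsyn_rate(self) -> np.ndarray:
        return self.posterior @ self.joint_nonsyn_rates

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "site": np.arange(1, self.posterior.shape[0] + 1),
            "mean_syn_rate": self.mean_syn_rate,
            "mean_nonsyn_rate": self.mean_nonsyn_rate,
        })


def posterior_site_rates(aln, tree, fit: DualRateResults,
                         _model: DualRateCodonModel | None = None
                         ) -> SiteRatePosterior:
    """Empirical Bayes: posterior category weights per site,
    posterior(site, cat) proportional to prior weight x site likelihood."""
    if not fit.converged:
        raise ValueError("posterior site rates require a converged fit")
    model = _model if _model is not None else DualRateCodonModel(
        aln, tree, kappa=fit.params["kappa"], estimate_kappa=False)
    dual = DualRateModel(
        params=model.codon_params(fit.params["kappa"]),
        syn_dist=fit.syn_dist, nonsyn_dist=fit.nonsyn_dist,
        nonsyn_scale=fit.params["nonsyn_scale"],
    )
    logl, w = model.engine.site_log_likelihoods_by_category(
        dual, fit.params["branch_scale"])
    log_post = logl + np.log(w)[None, :]
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    syn, nonsyn, _ = dual.joint_categories()
    return SiteRatePosterior(posterior=np.exp(log_post),
                             joint_syn_rates=syn, joint_nonsyn_rates=nonsyn,
                             prior_weights=np.asarray(w))


def fit_discrete_gamma(aln, tree, k_syn: int = 3, k_nonsyn: int | None = None,
                       **options) -> DualRateResults:
    """Fit the discrete-gamma dual-rate model (functional convenience
    wrapper over `DualRateCodonModel.fit`)."""
    model_opts = {k: options.pop(k) for k in ("kappa", "frequencies",
                                              "estimate_kappa") if k in options}
    model = DualRateCodonModel(aln, tree, **model_opts)
    return model.fit(method="discrete_gamma", k_syn=k_syn, k_nonsyn=k_nonsyn,
                     **options)


def fit_gdd(aln, tree, k_syn: int = 3, k_nonsyn: int | None = None,
            **options) -> DualRateResults:
    """Fit the general-discrete-distribution dual-rate model."""
    model_opts = {k: options.pop(k) for k in ("kappa", "frequencies",
                                              "estimate_kappa") if k in options}
    model = DualRateCodonModel(aln, tree, **model_opts)
    return model.fit(method="gdd", k_syn=k_syn, k_nonsyn=k_nonsyn, **options)
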