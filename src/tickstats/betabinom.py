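"""Beta-binomial logistic regression of con-specific mating proportions.

The response for each observation unit — one (animal, female species) with
at least one mated female — is the number of con-specifically mated
females out of all mated females in the unit.  Fixed effects are the
female species, the centred con-specific male and female proportions on
the animal (proportion − 0.5) and their interaction.  Extra-binomial
variation among females sharing a host is captured by an intraclass
correlation ``rho``: the beta-binomial with mean ``mu`` and shape
parameters ``mu (1 − rho) / rho`` and ``(1 − mu)(1 − rho) / rho``, which
degenerates to the binomial as ``rho → 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess

from tickstats.survey import SPECIES, TickObservation

ALL_TERMS: tuple[str, ...] = ("intercept", "species", "male", "female",
                              "interaction")
_MU_EPS = 1e-9
_RHO_BINOMIAL = 1e-8  # below this the binomial likelihood is used
_RHO_BOUNDARY = 1e-3


@dataclass
class BetaBinomDataset:
    """Aligned per-unit arrays for the mating regression."""

    trials: np.ndarray
    successes: np.ndarray
    female_species: np.ndarray  # "Av" / "Ah"
    x_male: np.ndarray          # centred con-specific male proportion
    x_female: np.ndarray        # centred con-specific female proportion
    animal_id: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=int)
        self.successes = np.asarray(self.successes, dtype=int)
        self.female_species = np.asarray(self.female_species, dtype=object)
        self.x_male = np.asarray(self.x_male, dtype=float)
        self.x_female = np.asarray(self.x_female, dtype=float)
        n = len(self.trials)
        for name in ("successes", "female_species", "x_male", "x_female"):
            if len(getattr(self, name)) != n:
                raise ValueError("misaligned arrays")
        if ((self.successes < 0) | (self.successes > self.trials)).any():
            raise ValueError("successes must lie in [0, trials]")
        if (np.abs(self.x_male) > 0.5 + 1e-12).any() or \
                (np.abs(self.x_female) > 0.5 + 1e-12).any():
            raise ValueError("centred covariates must lie in [-0.5, 0.5]")

    def __len__(self) -> int:
        return len(self.trials)

    def design_matrix(self, terms: Sequence[str] = ALL_TERMS) -> np.ndarray:
        cols = []
        for term in terms:
            if term == "intercept":
                cols.append(np.ones(len(self)))
            elif term == "species":
                cols.append((self.female_species == SPECIES[1]).astype(float))
            elif term == "male":
                cols.append(self.x_male)
            elif term == "female":
                cols.append(self.x_female)
            elif term == "interaction":
                cols.append(self.x_male * self.x_female)
            else:
                raise ValueError(f"unknown term {term!r}")
        return np.column_stack(cols)


def build_dataset(observations: Sequence[TickObservation]
                  ) -> BetaBinomDataset:
    """Aggregate a survey into one regression unit per (animal, female
    species) with at least one mated female.

    Covariates come from the animal's full adult tick composition: the
    proportion of its males (females) con-specific with the unit's female
    species, centred on 0.5.  Units on animals carrying no males are
    dropped with a warning (male covariate undefined).
    """
    males: dict[tuple, np.ndarray] = {}
    females: dict[tuple, np.ndarray] = {}
    mated: dict[tuple, list[TickObservation]] = {}
    for o in observations:
        animal = (o.site_id, o.animal_id)
        counts = males if o.sex == "M" else females
        counts.setdefault(animal, np.zeros(2))[SPECIES.index(o.species)] += 1
        if o.sex == "F" and o.partner_species in SPECIES:
            mated.setdefault(animal, []).append(o)

    rows: dict[str, list] = {k: [] for k in (
        "trials", "successes", "female_species", "x_male", "x_female",
        "animal_id")}
    n_dropped = 0
    for animal, mated_females in sorted(mated.items()):
        m = males.get(animal, np.zeros(2))
        f = females[animal]
        if m.sum() == 0:
            n_dropped += 1
            continue
        for species in SPECIES:
            unit = [o for o in mated_females if o.species == species]
            if not unit:
                continue
            j = SPECIES.index(species)
            rows["trials"].append(len(unit))
            rows["successes"].append(
                sum(1 for o in unit if o.partner_species == species))
            rows["female_species"].append(species)
            rows["x_male"].append(m[j] / m.sum() - 0.5)
            rows["x_female"].append(f[j] / f.sum() - 0.5)
            rows["animal_id"].append(animal)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} animals with mated females but "
                      "no males (male covariate undefined)", stacklevel=2)
    return BetaBinomDataset(
        trials=np.array(rows["trials"], dtype=int),
        successes=np.array(rows["successes"], dtype=int),
        female_species=np.array(rows["female_species"], dtype=object),
        x_male=np.array(rows["x_male"]),
        x_female=np.array(rows["x_female"]),
        animal_id=rows["animal_id"])


def betabinom_logpmf(k, n, mu, rho):
    """Log pmf of the (mu, rho)-parameterised beta-binomial.

    Vectorised; falls back to the binomial for ``rho`` below 1e-8.
    """
    mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
    if np.ndim(rho) == 0 and rho < _RHO_BINOMIAL:
        return stats.binom.logpmf(k, n, mu)
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    return stats.betabinom.logpmf(k, n, a, b)


def loglikelihood(beta: Sequence[float], rho: float,
                  dataset: BetaBinomDataset,
                  terms: Sequence[str] = ALL_TERMS) -> float:
    """Model log-likelihood at coefficients ``beta`` and correlation ``rho``."""
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    x = dataset.design_matrix(terms)
    mu = special.expit(x @ np.asarray(beta, dtype=float))
    return float(betabinom_logpmf(dataset.successes, dataset.trials, mu,
                                  rho).sum())


@dataclass
class BetaBinomFit:
    terms: tuple[str, ...]
    coef: dict[str, float]
    rho: float
    loglik: float
    cov: np.ndarray | None      # over (beta..., logit rho) when free
    se: dict[str, float]
    rho_se: float | None
    rho_p: float | None
    converged: bool
    boundary_rho: bool
    beta_binomial: bool
    n_units: int
    message: str = ""

    @property
    def n_params(self) -> int:
        return len(self.terms) + (1 if self.beta_binomial else 0)

    def beta_cov(self) -> np.ndarray | None:
        if self.cov is None:
            return None
        k = len(self.terms)
        return self.cov[:k, :k]


def _neg_loglik(params: np.ndarray, dataset, terms, beta_binomial) -> float:
    k = len(terms)
    beta = params[:k]
    rho = special.expit(params[k]) if beta_binomial else 0.0
    x = dataset.design_matrix(terms)
    mu = special.expit(x @ beta)
    ll = betabinom_logpmf(dataset.successes, dataset.trials, mu, rho).sum()
    return -ll if np.isfinite(ll) else 1e12


def fit(dataset: BetaBinomDataset, terms: Sequence[str] = ALL_TERMS,
        beta_binomial: bool = True, start: Sequence[float] | None = None,
        maxiter: int = 1000, gtol: float = 1e-7) -> BetaBinomFit:
    """Maximum-likelihood fit, optimised on the unconstrained scale.

    Coefficients are unconstrained; ``rho`` is optimised as ``logit(rho)``
    so the [0, 1) constraint stays interior.  The covariance comes from the
    inverse observed information at the optimum; ``rho``'s standard error
    and Wald p are delta-method transforms of the logit-scale ones.
    """
    terms = tuple(terms)
    n_params = len(terms) + (1 if beta_binomial else 0)
    if len(dataset) < n_params:
        raise ValueError("too few units to identify the parameters")
    k = len(terms)
    if start is None:
        p_bar = (dataset.successes.sum() + 0.5) / (dataset.trials.sum() + 1)
        start_beta = np.zeros(k)
        if "intercept" in terms:
            start_beta[terms.index("intercept")] = special.logit(p_bar)
        start = np.concatenate(
            [start_beta, [special.logit(0.1)]]) if beta_binomial \
            else start_beta
    start = np.asarray(start, dtype=float)

    starts = [start]
    if beta_binomial:
        # second start at the binomial MLE with rho pinned ~0; guarantees
        # the beta-binomial optimum never scores below its binomial
        # reduction even when the true rho is at the boundary
        res0 = optimize.minimize(
            _neg_loglik, start[:k], args=(dataset, terms, False),
            method="L-BFGS-B", options={"maxiter": maxiter, "gtol": gtol})
        starts.append(np.concatenate([res0.x, [special.logit(1e-9)]]))

    res = None
    for s in starts:
        cand = optimize.minimize(
            _neg_loglik, s, args=(dataset, terms, beta_binomial),
            method="L-BFGS-B", options={"maxiter": maxiter, "gtol": gtol})
        if res is None or cand.fun < res.fun:
            res = cand
    if not res.success:
        # one polish from the best point; L-BFGS-B line searches can stall
        res2 = optimize.minimize(
            _neg_loglik, res.x, args=(dataset, terms, beta_binomial),
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-8})
        if res2.fun <= res.fun:
            res = res2
    params = res.x
    loglik = -float(res.fun)
    beta = params[:k]
    rho = float(special.expit(params[k])) if beta_binomial else 0.0
    boundary = beta_binomial and (rho < _RHO_BOUNDARY or rho > 1 - 5e-2)
    if beta_binomial and not boundary:
        # rho unidentifiable (e.g. all trials = 1): likelihood flat in rho
        at_zero = params.copy()
        at_zero[k] = special.logit(1e-12)
        if abs(_neg_loglik(at_zero, dataset, terms, beta_binomial)
               - res.fun) < 1e-8:
            boundary = True

    cov = None
    rho_se = rho_p = None
    se = {t: np.nan for t in terms}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = approx_hess(
                params, lambda p: -_neg_loglik(p, dataset, terms,
                                               beta_binomial))
            cov = np.linalg.inv(-hess)
        diag = np.diag(cov)
        if (diag > 0).all():
            se = {t: float(np.sqrt(diag[i])) for i, t in enumerate(terms)}
            if beta_binomial:
                se_u = float(np.sqrt(diag[k]))
                rho_se = se_u * rho * (1 - rho)  # delta method from logit
                if rho_se > 0:
                    rho_p = float(2 * stats.norm.sf(rho / rho_se))
        else:
            cov = None
    except np.linalg.LinAlgError:
        cov = None

    return BetaBinomFit(
        terms=terms, coef={t: float(b) for t, b in zip(terms, beta)},
        rho=rho, loglik=loglik, cov=cov, se=se, rho_se=rho_se, rho_p=rho_p,
        converged=bool(res.success or res.fun < 1e11),
        boundary_rho=boundary, beta_binomial=beta_binomial,
        n_units=len(dataset), message=str(res.message))


@dataclass
class LRTResult:
    chi2: float
    df: int
    p: float


def lrt(fit_full: BetaBinomFit, fit_reduced: BetaBinomFit) -> LRTResult:
    """Likelihood-ratio test of nested fits on the same data."""
    if fit_full.n_units != fit_reduced.n_units:
        raise ValueError("fits are not on the same data")
    df = fit_full.n_params - fit_reduced.n_params
    if df <= 0:
        raise ValueError("reduced model must have fewer parameters")
    chi2 = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    if chi2 < -1e-6:
        raise ValueError(
            f"full model log-likelihood below reduced ({chi2/2:+.4g}); "
            "optimisation failed")
    chi2 = max(chi2, 0.0)
    return LRTResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


@dataclass
class PredictionSurface:
    p_male: np.ndarray    # grid of con-specific male proportions
    p_female: np.ndarray
    mean: np.ndarray      # mean[i, j] at (p_male[i], p_female[j])
    cv: np.ndarray | None

    def fraction_above(self, level: float = 0.5) -> float:
        """Fraction of the grid with predicted mean above ``level``."""
        return float((self.mean > level).mean())


def predict_surface(fitted: BetaBinomFit, n_grid: int = 101,
                    n_draws: int = 1000, seed: int | None = None,
                    species: str = "Av") -> PredictionSurface:
    """Predicted mean and coefficient of variation over the proportion grid.

    The CV is Monte-Carlo: coefficient draws from the asymptotic normal
    around the fit propagate through the inverse-logit mean.  With a
    singular covariance only the mean surface is returned.  ``species``
    selects the female-species level (``"average"`` for the midpoint).
    """
    if species not in (*SPECIES, "average"):
        raise ValueError(f"unknown species {species!r}")
    grid = np.linspace(0.0, 1.0, n_grid)
    pm, pf = np.meshgrid(grid, grid, indexing="ij")
    indicator = {SPECIES[0]: 0.0, SPECIES[1]: 1.0, "average": 0.5}[species]
    cols = {
        "intercept": np.ones_like(pm),
        "species": np.full_like(pm, indicator),
        "male": pm - 0.5,
        "female": pf - 0.5,
        "interaction": (pm - 0.5) * (pf - 0.5),
    }
    x = np.stack([cols[t] for t in fitted.terms], axis=-1)
    beta = np.array([fitted.coef[t] for t in fitted.terms])
    mean = special.expit(x @ beta)

    cv = None
    cov = fitted.beta_cov()
    if cov is not None:
        rng = np.random.default_rng(seed)
        try:
            draws = rng.multivariate_normal(beta, cov, size=n_draws,
                                            method="cholesky")
        except np.linalg.LinAlgError:
            draws = None
        if draws is not None:
            mu = special.expit(np.einsum("ijk,dk->dij", x, draws))
            m = mu.mean(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                cv = np.where(m > 0, mu.std(axis=0, ddof=1) / m, np.nan)
    return PredictionSurface(p_male=grid, p_female=grid.copy(), mean=mean,
                             cv=cv)
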