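"""Maximum-likelihood codon substitution models on a fixed 3-taxon tree.

The unrooted tree relates one outgroup (At, *A. thaliana*) and two ingroup
lineages (Ci, *C. impatiens*; Cr, *C. resedifolia*).  Substitution follows a
Goldman–Yang-style Markov process on the 61 sense codons with instantaneous
rates

    q_ij = 0                        if codons i and j differ at >1 position
    q_ij = pi_j                     synonymous transversion
    q_ij = kappa * pi_j             synonymous transition
    q_ij = omega * pi_j             non-synonymous transversion
    q_ij = kappa * omega * pi_j     non-synonymous transition

scaled so branch lengths are expected substitutions per codon site.  The model
zoo covers a single genome-wide omega (M0), one omega per branch (free-ratio),
two-ratio branch models with a chosen foreground lineage, the site-class
mixtures M1a/M2a and M7/M8 (beta-distributed omega in 10 equal-probability
categories), and branch-site model A with its test-2 null (foreground omega2
fixed to 1).  Nested pairs are compared by chi-square likelihood-ratio tests;
per-gene P values are corrected by FDR q-values.

The entry point is :class:`CodonModel`, statsmodels-style::

    model = CodonModel(alignment, ModelSpec("M0"))
    res = model.fit(seed=0)
    res.summary()

with :class:`CodonModelResults` carrying the MLEs, the maximized
log-likelihood, convergence diagnostics, and per-branch dN/dS via
:meth:`CodonModelResults.branch_rates`.

Per-branch dN and dS follow the mutational-opportunity convention: with L
codons, the synonymous site count is S = 3L * rho_S1 where rho_S1 is the
proportion of the total substitution rate that is synonymous under the same
matrix with omega := 1 (and N = 3L - S); then for a branch of length t,
dS = t * rho_S / (3 * rho_S1) and dN = t * rho_N / (3 * rho_N1), where
rho_S, rho_N partition the fitted matrix's rate.  Under this convention
dN/dS equals the model omega exactly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, optimize
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from .genetics import (
    CODON_NT,
    N_CODONS,
    PAIR_I,
    PAIR_J,
    PAIR_SYN,
    PAIR_TS,
    SENSE_CODONS,
    CODON_AA,
    codons_to_indices,
)

BRANCHES = ("At", "Ci", "Cr")

_MODELS = (
    "M0",
    "FR",
    "B2_Ci",
    "B2_Cr",
    "M1a",
    "M2a",
    "M7",
    "M8",
    "BSA_null",
    "BSA_alt",
)

# optimizer bounds (natural scale)
_B_KAPPA = (0.05, 50.0)
_B_OMEGA = (1e-4, 99.0)
_B_OMEGA01 = (1e-4, 0.999)
_B_OMEGA_GE1 = (1.0, 99.0)
_B_PROP = (1e-9, 1.0 - 1e-9)
_B_BETA = (0.005, 99.0)
_B_T = (0.0, 20.0)


# ---------------------------------------------------------------------------
# codon frequencies


@dataclass(frozen=True)
class CodonFrequencies:
    """Equilibrium codon frequencies pi over the 61 sense codons."""

    pi: np.ndarray
    scheme: str = "uniform"
    pos_freqs: Optional[np.ndarray] = None  # (3, 4) when scheme == "F3x4"

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (N_CODONS,):
            raise ValueError(f"pi must have {N_CODONS} entries")
        if np.any(pi < 0):
            raise ValueError("pi entries must be non-negative")
        if not np.isclose(pi.sum(), 1.0, atol=1e-8):
            raise ValueError("pi must sum to 1")
        if np.any(pi == 0):
            warnings.warn(
                "pi contains zero entries; the corresponding codons become "
                "unreachable (absorbing for the reverse chain); flooring at 1e-8",
                stacklevel=2,
            )
            pi = np.maximum(pi, 1e-8)
            pi = pi / pi.sum()
        object.__setattr__(self, "pi", pi)

    @classmethod
    def uniform(cls) -> "CodonFrequencies":
        return cls(np.full(N_CODONS, 1.0 / N_CODONS), scheme="uniform")

    @classmethod
    def f61(cls, codon_matrix: np.ndarray) -> "CodonFrequencies":
        """Empirical codon frequencies with a pseudocount of 1."""
        counts = np.bincount(np.asarray(codon_matrix).ravel(), minlength=N_CODONS)
        pi = (counts + 1.0) / (counts.sum() + N_CODONS)
        return cls(pi, scheme="F61")

    @classmethod
    def f3x4(cls, codon_matrix: np.ndarray) -> "CodonFrequencies":
        """Position-specific nucleotide frequencies multiplied out over the
        sense codons (stop-codon mass renormalized away)."""
        mat = np.asarray(codon_matrix)
        nts = CODON_NT[mat]  # (..., 3) nucleotide indices per position
        pos = np.empty((3, 4))
        for p in range(3):
            c = np.bincount(nts[..., p].ravel(), minlength=4).astype(float)
            c = np.maximum(c, 1e-4)  # guard empty nucleotide classes
            pos[p] = c / c.sum()
        pi = pos[0][CODON_NT[:, 0]] * pos[1][CODON_NT[:, 1]] * pos[2][CODON_NT[:, 2]]
        pi = pi / pi.sum()
        return cls(pi, scheme="F3x4", pos_freqs=pos)


# ---------------------------------------------------------------------------
# rate matrix and transition probabilities


def _unscaled_q(kappa: float, omega: float, pi: np.ndarray):
    """Unscaled generator and its mean rate.

    Returns (Q, rate) with q_ij proportional to pi_j, times kappa for
    transitions and omega for non-synonymous changes; rate = -sum pi_i q_ii.
    """
    rates = pi[PAIR_J] * np.where(PAIR_TS, kappa, 1.0) * np.where(PAIR_SYN, 1.0, omega)
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[PAIR_I, PAIR_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -float(pi @ np.diag(Q))
    return Q, rate


def build_rate_matrix(kappa: float, omega: float, pi: CodonFrequencies | np.ndarray) -> np.ndarray:
    """Goldman–Yang generator scaled to mean rate 1 (time-reversible w.r.t. pi).

    omega = 0 is allowed (forbids all non-synonymous moves), as needed for
    forward simulation of fully constrained sites.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    pvec = pi.pi if isinstance(pi, CodonFrequencies) else np.asarray(pi, dtype=float)
    Q, rate = _unscaled_q(kappa, omega, pvec)
    if rate <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q / rate


def _stationary(Q: np.ndarray) -> np.ndarray:
    w, v = linalg.eig(Q.T)
    k = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def transition_probabilities(Q: np.ndarray, t: float, pi: Optional[np.ndarray] = None) -> np.ndarray:
    """P(t) = exp(Qt), via symmetrized eigendecomposition when Q is reversible.

    Falls back to scaling-and-squaring (scipy expm) with a warning otherwise.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if pi is None:
        pi = _stationary(Q)
    flux = pi[:, None] * Q
    if np.allclose(flux, flux.T, atol=1e-10):
        d = np.sqrt(pi)
        S = (d[:, None] * Q) / d[None, :]
        lam, U = linalg.eigh(S)
        A = U / d[:, None]
        B = U.T * d[None, :]
        P = (A * np.exp(lam * t)) @ B
    else:
        warnings.warn("non-reversible generator; using scaling-and-squaring", stacklevel=2)
        P = linalg.expm(Q * t)
    P = np.maximum(P, 0.0)
    P /= P.sum(axis=1, keepdims=True)
    return P


class _EigenCache:
    """Per-model cache of eigendecompositions of unscaled generators.

    Keyed by exact (kappa, omega) floats: during finite-difference gradient
    steps most coordinates leave the generator unchanged, so this removes the
    dominant eigendecomposition cost from branch-length and proportion moves.
    """

    def __init__(self, pi: np.ndarray, maxsize: int = 512):
        self.pi = pi
        self._d = np.sqrt(pi)
        self._store: dict[tuple[float, float], tuple] = {}
        self.maxsize = maxsize

    def get(self, kappa: float, omega: float):
        key = (kappa, omega)
        hit = self._store.get(key)
        if hit is None:
            Q, rate = _unscaled_q(kappa, omega, self.pi)
            S = (self._d[:, None] * Q) / self._d[None, :]
            lam, U = np.linalg.eigh(S)
            A = U / self._d[:, None]
            B = U.T * self._d[None, :]
            hit = (lam, A, B, rate)
            if len(self._store) >= self.maxsize:
                self._store.clear()
            self._store[key] = hit
        return hit

    def prob(self, kappa: float, omega: float, tau: float) -> np.ndarray:
        """exp(Q_unscaled * tau)."""
        lam, A, B, _ = self.get(kappa, omega)
        return (A * np.exp(lam * tau)) @ B

    def rate(self, kappa: float, omega: float) -> float:
        return self.get(kappa, omega)[3]


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class PhyloTree:
    """The fixed unrooted 3-taxon topology (At, Ci, Cr) with branch lengths
    in expected substitutions per codon site."""

    t_At: float = 0.1
    t_Ci: float = 0.05
    t_Cr: float = 0.05

    def __post_init__(self):
        for b in BRANCHES:
            if getattr(self, f"t_{b}") < 0:
                raise ValueError("branch lengths must be >= 0")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.t_At, self.t_Ci, self.t_Cr])

    @classmethod
    def from_newick(cls, s: str, lengths: Optional[Sequence[float]] = None) -> "PhyloTree":
        """Accepts the fixed topology string '(At,Ci,Cr);' for interface
        symmetry; only the tip set is checked."""
        tips = {x.split(":")[0].strip() for x in s.strip().rstrip(";").strip("()").split(",")}
        if tips != set(BRANCHES):
            raise ValueError(f"expected tips {BRANCHES}, got {sorted(tips)}")
        if lengths is None:
            return cls()
        return cls(*lengths)


@dataclass(frozen=True)
class ModelSpec:
    """A codon substitution model identifier plus its foreground branch
    (required for the two-ratio branch models and branch-site model A)."""

    model: str
    foreground: Optional[str] = None

    def __post_init__(self):
        m = self.model
        if m in ("B2_Ci", "B2_Cr"):
            object.__setattr__(self, "foreground", m.split("_")[1])
        if m not in _MODELS:
            raise ValueError(f"unknown model {m!r}; choose from {_MODELS}")
        if m.startswith("BSA") and self.foreground not in ("Ci", "Cr"):
            raise ValueError("branch-site models need foreground 'Ci' or 'Cr'")

    @property
    def is_branch_site(self) -> bool:
        return self.model.startswith("BSA")


def _param_names(spec: ModelSpec) -> list[str]:
    m = spec.model
    if m == "M0":
        base = ["kappa", "omega"]
    elif m == "FR":
        base = ["kappa", "omega_At", "omega_Ci", "omega_Cr"]
    elif m in ("B2_Ci", "B2_Cr"):
        base = ["kappa", "omega_back", "omega_fore"]
    elif m == "M1a":
        base = ["kappa", "p0", "omega0"]
    elif m == "M2a":
        base = ["kappa", "q1", "q2", "omega0", "omega2"]
    elif m == "M7":
        base = ["kappa", "beta_p", "beta_q"]
    elif m == "M8":
        base = ["kappa", "beta_p", "beta_q", "p0", "omega_s"]
    elif m == "BSA_null":
        base = ["kappa", "q1", "q2", "omega0"]
    elif m == "BSA_alt":
        base = ["kappa", "q1", "q2", "omega0", "omega2"]
    return base + ["t_At", "t_Ci", "t_Cr"]


def _param_bounds(spec: ModelSpec) -> list[tuple[float, float]]:
    m = spec.model
    if m == "M0":
        b = [_B_KAPPA, _B_OMEGA]
    elif m == "FR":
        b = [_B_KAPPA, _B_OMEGA, _B_OMEGA, _B_OMEGA]
    elif m in ("B2_Ci", "B2_Cr"):
        b = [_B_KAPPA, _B_OMEGA, _B_OMEGA]
    elif m == "M1a":
        b = [_B_KAPPA, _B_PROP, _B_OMEGA01]
    elif m == "M2a":
        b = [_B_KAPPA, _B_PROP, _B_PROP, _B_OMEGA01, _B_OMEGA_GE1]
    elif m == "M7":
        b = [_B_KAPPA, _B_BETA, _B_BETA]
    elif m == "M8":
        b = [_B_KAPPA, _B_BETA, _B_BETA, _B_PROP, _B_OMEGA_GE1]
    elif m == "BSA_null":
        b = [_B_KAPPA, _B_PROP, _B_PROP, _B_OMEGA01]
    elif m == "BSA_alt":
        b = [_B_KAPPA, _B_PROP, _B_PROP, _B_OMEGA01, _B_OMEGA_GE1]
    return b + [_B_T, _B_T, _B_T]


_BETA_QUANTILES = (2 * np.arange(10) + 1) / 20.0


def _beta_categories(p: float, q: float) -> np.ndarray:
    """Medians of 10 equal-probability categories of Beta(p, q)."""
    return np.clip(beta_dist.ppf(_BETA_QUANTILES, p, q), 1e-8, 1.0 - 1e-9)


def _site_classes(spec: ModelSpec, x: np.ndarray) -> list[tuple[float, tuple[float, float, float]]]:
    """(weight, per-branch omega triple in (At, Ci, Cr) order) per site class."""
    m = spec.model
    if m == "M0":
        w = x[1]
        return [(1.0, (w, w, w))]
    if m == "FR":
        return [(1.0, (x[1], x[2], x[3]))]
    if m in ("B2_Ci", "B2_Cr"):
        back, fore = x[1], x[2]
        om = {b: (fore if b == spec.foreground else back) for b in BRANCHES}
        return [(1.0, (om["At"], om["Ci"], om["Cr"]))]
    if m == "M1a":
        p0, w0 = x[1], x[2]
        return [(p0, (w0,) * 3), (1.0 - p0, (1.0,) * 3)]
    if m == "M2a":
        q1, q2, w0, w2 = x[1], x[2], x[3], x[4]
        p0 = q1
        p1 = (1.0 - q1) * q2
        p2 = (1.0 - q1) * (1.0 - q2)
        return [(p0, (w0,) * 3), (p1, (1.0,) * 3), (p2, (w2,) * 3)]
    if m == "M7":
        cats = _beta_categories(x[1], x[2])
        return [(0.1, (w, w, w)) for w in cats]
    if m == "M8":
        cats = _beta_categories(x[1], x[2])
        p0, ws = x[3], x[4]
        out = [(p0 / 10.0, (w, w, w)) for w in cats]
        out.append((1.0 - p0, (ws,) * 3))
        return out
    # branch-site model A
    q1, q2, w0 = x[1], x[2], x[3]
    w2 = 1.0 if m == "BSA_null" else x[4]
    p0 = q1 * q2
    p1 = q1 * (1.0 - q2)
    p2a = (1.0 - q1) * q2
    p2b = (1.0 - q1) * (1.0 - q2)
    fg = spec.foreground

    def trip(back: float, fore: float):
        return tuple(fore if b == fg else back for b in BRANCHES)

    return [
        (p0, trip(w0, w0)),
        (p1, trip(1.0, 1.0)),
        (p2a, trip(w0, w2)),
        (p2b, trip(1.0, w2)),
    ]


# ---------------------------------------------------------------------------
# the model


class CodonModel:
    """Likelihood model for one trimmed codon alignment on the fixed triplet
    tree.

    Parameters
    ----------
    alignment : (3, L) integer array of sense-codon indices in (At, Ci, Cr)
        row order, or any object with a ``codon_matrix`` attribute of that
        shape (e.g. ``TrimmedCodonAlignment``).
    spec : ModelSpec
    freqs : CodonFrequencies, optional
        Defaults to F3x4 estimated from the alignment.
    """

    def __init__(self, alignment, spec: ModelSpec | str, freqs: Optional[CodonFrequencies] = None):
        mat = np.asarray(getattr(alignment, "codon_matrix", alignment))
        if mat.ndim != 2 or mat.shape[0] != 3:
            raise ValueError("alignment must be a (3, L) codon-index matrix")
        if mat.shape[1] < 1:
            raise ValueError("empty alignment")
        if isinstance(spec, str):
            spec = ModelSpec(spec)
        self.spec = spec
        self.ncodons = mat.shape[1]
        if self.ncodons < 30:
            warnings.warn(
                f"alignment has only {self.ncodons} codons; estimates will be noisy",
                stacklevel=2,
            )
        self.freqs = freqs if freqs is not None else CodonFrequencies.f3x4(mat)
        patterns, counts = np.unique(mat.T, axis=0, return_counts=True)
        self._pat = patterns.T.astype(np.intp)  # (3, npat)
        self._cnt = counts.astype(float)
        self._cache = _EigenCache(self.freqs.pi)
        self.param_names = _param_names(spec)
        self.bounds = _param_bounds(spec)
        self.k_params = len(self.param_names)

    # -- likelihood ---------------------------------------------------------

    def loglike(self, x: np.ndarray | dict) -> float:
        """Log-likelihood at a parameter vector (or name->value dict),
        by pruning over the single internal node of the unrooted star."""
        if isinstance(x, dict):
            x = np.array([x[n] for n in self.param_names])
        x = np.asarray(x, dtype=float)
        kappa = x[0]
        t = x[-3:]
        classes = _site_classes(self.spec, x)
        pi = self.freqs.pi
        # per-branch scaling: mean rate over site classes equals 1
        site_lik = np.zeros(self._pat.shape[1])
        factors = []
        for b in range(3):
            f = sum(w * self._cache.rate(kappa, om[b]) for w, om in classes)
            factors.append(max(f, 1e-12))
        for w, om in classes:
            partial = np.ones((N_CODONS, self._pat.shape[1]))
            for b in range(3):
                P = self._cache.prob(kappa, om[b], t[b] / factors[b])
                partial *= P[:, self._pat[b]]
            site_lik += w * (pi @ partial)
        return float(self._cnt @ np.log(np.maximum(site_lik, 1e-300)))

    # -- starting values ----------------------------------------------------

    def _distance_start(self) -> dict[str, float]:
        """Cheap Jukes–Cantor distance heuristics for branch lengths."""
        nts = CODON_NT[self._pat.T].reshape(-1, 3, 3).transpose(1, 0, 2).reshape(3, -1)
        wts = np.repeat(self._cnt, 3)

        def jc(a, b):
            p = float(((nts[a] != nts[b]) * wts).sum() / wts.sum())
            p = min(p, 0.70)
            return -0.75 * np.log(1 - 4.0 * p / 3.0)

        d_ac, d_ar, d_cr = jc(0, 1), jc(0, 2), jc(1, 2)
        # nucleotide distances -> codon-scale branch lengths (x3 sites/codon)
        t = {
            "t_At": 3 * max((d_ac + d_ar - d_cr) / 2, 1e-3 / 3),
            "t_Ci": 3 * max((d_ac + d_cr - d_ar) / 2, 1e-3 / 3),
            "t_Cr": 3 * max((d_ar + d_cr - d_ac) / 2, 1e-3 / 3),
        }
        return t

    def start_params(self) -> np.ndarray:
        """Deterministic starting vector (distance-based branch lengths plus
        model-specific defaults)."""
        t = self._distance_start()
        defaults = {
            "kappa": 2.0,
            "omega": 0.3,
            "omega_At": 0.3,
            "omega_Ci": 0.3,
            "omega_Cr": 0.3,
            "omega_back": 0.3,
            "omega_fore": 0.3,
            "p0": 0.8,
            "q1": 0.8,
            "q2": 0.85,
            "omega0": 0.1,
            "omega2": 1.5,
            "omega_s": 1.5,
            "beta_p": 0.3,
            "beta_q": 1.2,
            **t,
        }
        x = np.array([defaults[n] for n in self.param_names])
        return self._clip(x)

    def _clip(self, x: np.ndarray) -> np.ndarray:
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return np.clip(x, lo, hi)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        start: Optional[np.ndarray | dict] = None,
        restarts: int = 3,
        seed: int = 0,
        maxiter: int = 500,
    ) -> "CodonModelResults":
        """Maximize the log-likelihood by bounded L-BFGS-B from one
        deterministic start (plus ``start`` if given) and ``restarts`` seeded
        random restarts; the best optimum is returned."""
        starts = []
        if start is not None:
            if isinstance(start, dict):
                base = {n: v for n, v in zip(self.param_names, self.start_params())}
                base.update(start)
                start = np.array([base[n] for n in self.param_names])
            starts.append(self._clip(np.asarray(start, dtype=float)))
        det = self.start_params()
        starts.append(det)
        rng = np.random.default_rng(seed)
        for _ in range(restarts):
            jitter = det * np.exp(rng.normal(0.0, 0.5, size=det.shape))
            starts.append(self._clip(jitter))

        neg = lambda x: -self.loglike(x)
        best = None
        nfev = 0
        for x0 in starts:
            res = optimize.minimize(
                neg,
                x0,
                method="L-BFGS-B",
                bounds=self.bounds,
                options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-7},
            )
            nfev += res.nfev
            if best is None or res.fun < best.fun:
                best = res
        converged = bool(best.success)
        if not converged:
            warnings.warn(
                f"{self.spec.model}: optimizer did not report convergence "
                f"({best.message}); returning best point found",
                stacklevel=2,
            )
        return CodonModelResults(
            model=self,
            spec=self.spec,
            params_vector=np.asarray(best.x),
            llf=-float(best.fun),
            converged=converged,
            n_starts=len(starts),
            nfev=nfev,
            grad_norm=float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan,
        )


@dataclass
class CodonModelResults:
    """Fit results: MLEs, maximized log-likelihood and diagnostics."""

    model: CodonModel
    spec: ModelSpec
    params_vector: np.ndarray
    llf: float
    converged: bool
    n_starts: int
    nfev: int
    grad_norm: float = np.nan

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(self.model.param_names, self.params_vector))

    @property
    def k_params(self) -> int:
        return self.model.k_params

    @property
    def tree(self) -> PhyloTree:
        p = self.params
        return PhyloTree(p["t_At"], p["t_Ci"], p["t_Cr"])

    def site_class_table(self) -> list[tuple[float, tuple[float, float, float]]]:
        """Fitted (weight, per-branch omega) per site class."""
        return _site_classes(self.spec, self.params_vector)

    def branch_rates(self) -> "BranchRates":
        return branch_rates(self)

    def lrt(self, null: "CodonModelResults", df_override: Optional[int] = None) -> "LRTResult":
        return lrt(null, self, df_override=df_override)

    def summary(self) -> str:
        lines = [
            f"Codon substitution model {self.spec.model}"
            + (f" (foreground {self.spec.foreground})" if self.spec.foreground else ""),
            f"  codons: {self.model.ncodons}   codon freqs: {self.model.freqs.scheme}",
            f"  log-likelihood: {self.llf:.6f}   free parameters: {self.k_params}",
            f"  converged: {self.converged}   starts: {self.n_starts}   nfev: {self.nfev}",
            "  parameter estimates:",
        ]
        for n, v in self.params.items():
            lines.append(f"    {n:>10s} = {v:.6f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# per-branch rates


@dataclass
class BranchRates:
    """Per-branch dN, dS and omega plus the mutational-opportunity site
    counts N and S (shared across branches)."""

    branches: dict[str, dict[str, float]]
    N: float
    S: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.branches).T


def branch_rates(fit: CodonModelResults) -> BranchRates:
    """Decompose fitted branch lengths into dN and dS per branch.

    Valid for single-class models (M0, FR, B2); the convention is documented
    in the module docstring.  omega is flagged undefined (NaN) when dS = 0.
    """
    spec = fit.spec
    if spec.model not in ("M0", "FR", "B2_Ci", "B2_Cr"):
        raise ValueError("branch rates are defined for the branch models (M0/FR/B2)")
    x = fit.params_vector
    kappa = x[0]
    (_, omegas), = _site_classes(spec, x)
    pi = fit.model.freqs.pi
    L = fit.model.ncodons

    _, rate1 = _unscaled_q(kappa, 1.0, pi)
    syn_flux1 = float((pi[PAIR_I] * pi[PAIR_J] * np.where(PAIR_TS, kappa, 1.0))[PAIR_SYN].sum())
    rho_s1 = syn_flux1 / rate1
    rho_n1 = 1.0 - rho_s1
    S = 3.0 * L * rho_s1
    N = 3.0 * L - S

    t = fit.params_vector[-3:]
    out = {}
    for b, name in enumerate(BRANCHES):
        om = omegas[b]
        _, rate = _unscaled_q(kappa, om, pi)
        rho_s = syn_flux1 / rate
        rho_n = 1.0 - rho_s
        dS = t[b] * rho_s / (3.0 * rho_s1)
        dN = t[b] * rho_n / (3.0 * rho_n1)
        w = dN / dS if dS > 0 else np.nan
        out[name] = {"t": float(t[b]), "dN": float(dN), "dS": float(dS), "omega": float(w)}
    return BranchRates(branches=out, N=float(N), S=float(S))


# ---------------------------------------------------------------------------
# likelihood-ratio tests and FDR


@dataclass
class LRTResult:
    null_model: str
    alt_model: str
    statistic: float
    df: int
    pvalue: float
    qvalue: Optional[float] = None


def lrt(
    null_fit: CodonModelResults,
    alt_fit: CodonModelResults,
    df_override: Optional[int] = None,
) -> LRTResult:
    """Chi-square likelihood-ratio test of two nested fits.

    df defaults to the free-parameter-count difference; ``df_override``
    substitutes a stated value (e.g. 3 for the one-ratio vs free-ratio
    comparison under the branches-minus-one convention).
    """
    if alt_fit.k_params <= null_fit.k_params:
        raise ValueError("alternative model must have more free parameters")
    delta = alt_fit.llf - null_fit.llf
    if delta < -1e-6:
        raise RuntimeError(
            f"nesting violated: alt lnL {alt_fit.llf:.6f} < null lnL "
            f"{null_fit.llf:.6f}; optimization failure"
        )
    stat = max(0.0, 2.0 * delta)
    df = df_override if df_override is not None else alt_fit.k_params - null_fit.k_params
    p = float(chi2.sf(stat, df))
    return LRTResult(null_fit.spec.model, alt_fit.spec.model, stat, df, p)


def nested_start(alt_spec: ModelSpec | str, null_fit: CodonModelResults) -> dict[str, float]:
    """Starting values for an alternative model embedding a fitted null.

    Used to warm-start M0->FR/B2, M1a->M2a, M7->M8 and BSA_null->BSA_alt fits
    so the alternative optimum can never fall below the null optimum.
    """
    if isinstance(alt_spec, str):
        alt_spec = ModelSpec(alt_spec)
    null = null_fit.params
    m_alt, m_null = alt_spec.model, null_fit.spec.model
    out = {k: v for k, v in null.items() if k.startswith("t_") or k == "kappa"}
    if m_null == "M0":
        if m_alt == "FR":
            out.update({f"omega_{b}": null["omega"] for b in BRANCHES})
        elif m_alt.startswith("B2"):
            out.update({"omega_back": null["omega"], "omega_fore": null["omega"]})
        else:
            raise ValueError(f"no embedding of M0 in {m_alt}")
    elif (m_null, m_alt) == ("M1a", "M2a"):
        out.update({"q1": null["p0"], "q2": 1.0 - 1e-9, "omega0": null["omega0"], "omega2": 1.0})
    elif (m_null, m_alt) == ("M7", "M8"):
        # p0 at its bound makes the embedding exact to within the bound gap
        out.update(
            {"beta_p": null["beta_p"], "beta_q": null["beta_q"], "p0": 1.0 - 1e-9, "omega_s": 1.0}
        )
    elif (m_null, m_alt) == ("BSA_null", "BSA_alt"):
        out.update({"q1": null["q1"], "q2": null["q2"], "omega0": null["omega0"], "omega2": 1.0})
    else:
        raise ValueError(f"no embedding of {m_null} in {m_alt}")
    return out


def fdr_qvalues(pvalues: Sequence[float], method: str = "bh") -> np.ndarray:
    """q-values for a family of P values.

    method="bh": Benjamini–Hochberg step-up (default).  method="storey":
    BH scaled by Storey's pi0 estimated at lambda = 0.5.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    if method == "storey":
        pi0 = min(1.0, float((p > 0.5).mean()) / 0.5) if m else 1.0
        pi0 = max(pi0, 1.0 / m)
        q = np.minimum(q * pi0, 1.0)
    elif method != "bh":
        raise ValueError("method must be 'bh' or 'storey'")
    return q


# ---------------------------------------------------------------------------
# Nei–Gojobori (1986) counting estimator


@dataclass
class NG86Result:
    """Pairwise counting estimates: proportions, Jukes–Cantor-corrected rates
    and site counts.  ``dn``/``ds`` are NaN with ``saturated`` set when the
    correction's argument is non-positive."""

    pn: float
    ps: float
    dn: float
    ds: float
    N: float
    S: float
    nd: float
    sd: float
    saturated: bool = False

    @property
    def omega(self) -> float:
        if self.ds is None or not np.isfinite(self.ds) or self.ds == 0:
            return np.nan
        return self.dn / self.ds


_SYN_SITES = np.zeros(N_CODONS)
for _i in range(N_CODONS):
    _SYN_SITES[_i] = PAIR_SYN[PAIR_I == _i].sum() / 3.0


def _pathway_counts(i: int, j: int) -> tuple[float, float]:
    """Average synonymous/non-synonymous step counts over minimal pathways
    between two codons, skipping pathways through stop codons."""
    ci, cj = SENSE_CODONS[i], SENSE_CODONS[j]
    diffs = [p for p in range(3) if ci[p] != cj[p]]
    results = []
    for order in itertools.permutations(diffs):
        cur = ci
        sd = nd = 0
        ok = True
        for p in order:
            nxt = cur[:p] + cj[p] + cur[p + 1 :]
            if nxt not in SENSE_CODONS and len(diffs) > 1:
                ok = False
                break
            if CODON_AA[SENSE_CODONS.index(cur)] == CODON_AA[SENSE_CODONS.index(nxt)]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        # all pathways cross a stop codon: count every step non-synonymous
        results = [(0, len(diffs))]
    sd = float(np.mean([r[0] for r in results]))
    nd = float(np.mean([r[1] for r in results]))
    return sd, nd


_PATH_CACHE: dict[tuple[int, int], tuple[float, float]] = {}


def ng86_rates(seq_a, seq_b) -> NG86Result:
    """Nei–Gojobori counting estimates for one in-frame ungapped codon pair.

    Accepts nucleotide strings or codon-index arrays of equal codon length.
    """
    a = codons_to_indices(seq_a) if isinstance(seq_a, str) else np.asarray(seq_a)
    b = codons_to_indices(seq_b) if isinstance(seq_b, str) else np.asarray(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal codon length")
    S = float((_SYN_SITES[a].sum() + _SYN_SITES[b].sum()) / 2.0)
    N = 3.0 * a.size - S
    sd = nd = 0.0
    for i, j in zip(a[a != b], b[a != b]):
        key = (int(i), int(j))
        if key not in _PATH_CACHE:
            _PATH_CACHE[key] = _pathway_counts(*key)
        s, n = _PATH_CACHE[key]
        sd += s
        nd += n
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0

    def jc(p):
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            return np.nan, True
        return -0.75 * float(np.log(arg)), False

    ds, sat_s = jc(ps)
    dn, sat_n = jc(pn)
    return NG86Result(pn=pn, ps=ps, dn=dn, ds=ds, N=N, S=S, nd=nd, sd=sd, saturated=sat_s or sat_n)


# functional wrappers matching the operation-style surface -------------------


def log_likelihood(alignment, tree: PhyloTree, spec: ModelSpec | str, params: dict) -> float:
    """Log-likelihood of an alignment at explicit parameter values."""
    model = CodonModel(alignment, spec)
    full = dict(params)
    full.setdefault("t_At", tree.t_At)
    full.setdefault("t_Ci", tree.t_Ci)
    full.setdefault("t_Cr", tree.t_Cr)
    return model.loglike(full)


def fit_model(
    alignment, spec: ModelSpec | str, restarts: int = 3, seed: int = 0, start=None
) -> CodonModelResults:
    """Fit a codon model to an alignment (thin wrapper over CodonModel.fit)."""
    return CodonModel(alignment, spec).fit(start=start, restarts=restarts, seed=seed)
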