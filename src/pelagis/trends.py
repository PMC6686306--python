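"""Penalized-smooth trend models for daily activity proportions.

The daily proportion of at-sea time spent in one activity (foraging, sustained
flight or floating), within one light period (daylight or darkness), is
modelled on the logit scale as

    logit E[y] = a + status + f_status(days since laying) + f_cyc(moon age)
                 + b_bird [+ g_bird(days)]

with a quasi-binomial variance (binomial form times a free dispersion
estimated from the Pearson statistic).  f_status are group-level penalized
cubic B-spline smooths (12 basis functions, second-difference penalty, one
smooth per breeding status); f_cyc is a cyclic cubic spline (k = 3) over the
29.53-day lunar cycle; b_bird are ridge-penalized random intercepts; g_bird
are optional low-rank per-individual deviation smooths, each with its own
smoothing parameter.  Smoothing parameters are chosen by generalized
cross-validation (GCV) with a grid-plus-golden-section search per term inside
a backfitting-style outer loop, and fitting is penalized iteratively
reweighted least squares (PIRLS).  Exposure (at-sea minutes) enters as the
binomial-denominator weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, logit

from .moon import SYNODIC_MONTH_DAYS
from .spatial import bootstrap_group_difference

logger = logging.getLogger(__name__)

ACTIVITIES = ("foraging", "flight", "float")
PERIODS = ("daylight", "darkness")
_EPS = 1e-6


class ConvergenceError(RuntimeError):
    """PIRLS failed to converge or produced a degenerate system."""


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------


def build_dataset(budgets: pd.DataFrame, records) -> pd.DataFrame:
    """Long-format modelling dataset from daily budgets and breeding records.

    One row per individual x date x period x activity, with the proportion of
    at-sea time, the exposure weight (at-sea minutes of that period), days
    since the individual's laying date, and the lunar age in days (the cyclic
    moon covariate; 0 = new moon).  Rows with zero at-sea time are dropped;
    individuals without a laying date are excluded (logged).
    """
    meta = {}
    for r in records:
        if r.laying_date is None:
            logger.info("build_dataset: %s excluded (no laying date)", r.individual_id)
            continue
        meta[r.individual_id] = (r.status, r.sex)
    rows = []
    prop_cols = {"foraging": "prop_foraging", "flight": "prop_flight", "float": "prop_float"}
    b = budgets[budgets["individual_id"].isin(meta) & (budgets["atsea_min"] > 0)]
    for act, col in prop_cols.items():
        if (b[col] < -1e-9).any() or (b[col] > 1 + 1e-9).any():
            raise ValueError("activity proportions must lie in [0, 1]")
        sub = pd.DataFrame(
            {
                "individual_id": b["individual_id"],
                "status": b["individual_id"].map(lambda i: meta[i][0]),
                "sex": b["individual_id"].map(lambda i: meta[i][1]),
                "days_since_laying": b["days_since_laying"].astype(float),
                "moon": b["moon"].astype(float),
                "moon_age": _moon_age_from_dates(b["date"]),
                "period": b["period"],
                "activity": act,
                "proportion": b[col].clip(0.0, 1.0).astype(float),
                "weight": b["atsea_min"].astype(float),
            }
        )
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def _moon_age_from_dates(dates) -> np.ndarray:
    from .moon import moon_age

    return moon_age(pd.to_datetime(dates).to_numpy())


# ---------------------------------------------------------------------------
# Bases and penalties
# ---------------------------------------------------------------------------


def bspline_basis(x: np.ndarray, n_basis: int, lo: float, hi: float, degree: int = 3) -> np.ndarray:
    """Cubic B-spline basis with ``n_basis`` functions on [lo, hi]."""
    n_inner = n_basis - degree - 1
    if n_inner < 0:
        raise ValueError("n_basis too small for cubic splines")
    inner = np.linspace(lo, hi, n_inner + 2)[1:-1]
    knots = np.concatenate([[lo] * (degree + 1), inner, [hi] * (degree + 1)])
    xc = np.clip(np.asarray(x, dtype=float), lo, hi)
    return BSpline.design_matrix(xc, knots, degree).toarray()


def difference_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    """S = D'D with D the ``order``-th difference matrix (curvature penalty)."""
    d = np.eye(n_basis)
    for _ in range(order):
        d = np.diff(d, axis=0)
    return d.T @ d


def _cardinal_cubic(u: np.ndarray) -> np.ndarray:
    """Cardinal cubic B-spline, support [-2, 2], unit knot spacing."""
    a = np.abs(np.asarray(u, dtype=float))
    out = np.zeros_like(a)
    m1 = a <= 1
    out[m1] = 2.0 / 3.0 - a[m1] ** 2 + a[m1] ** 3 / 2.0
    m2 = (a > 1) & (a <= 2)
    out[m2] = (2.0 - a[m2]) ** 3 / 6.0
    return out


def cyclic_basis(x: np.ndarray, period: float = SYNODIC_MONTH_DAYS, n_basis: int = 3) -> np.ndarray:
    """Periodic cubic B-spline basis: f and f' match at the period endpoints.

    Built from wrapped cardinal cubic B-splines at ``n_basis`` evenly spaced
    centres; rows sum to 1 and every basis function is exactly periodic.
    """
    x = np.mod(np.asarray(x, dtype=float), period)
    delta = period / n_basis
    cols = []
    for j in range(n_basis):
        c = j * delta
        val = np.zeros_like(x)
        for m in (-2, -1, 0, 1, 2):
            val += _cardinal_cubic((x - c + m * period) / delta)
        cols.append(val)
    return np.column_stack(cols)


def cyclic_penalty(n_basis: int) -> np.ndarray:
    """Circular second-difference penalty for a periodic basis."""
    d = np.zeros((n_basis, n_basis))
    for i in range(n_basis):
        d[i, i] = -2.0
        d[i, (i - 1) % n_basis] = 1.0
        d[i, (i + 1) % n_basis] = 1.0
    return d.T @ d


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class _Term:
    name: str
    sl: slice
    penalty: np.ndarray  # penalty block for the term's columns
    lam: float = 1.0
    searchable: bool = True
    transform: np.ndarray | None = None  # constraint-absorbing reparameterization


def _absorb_constant(block: np.ndarray, penalty: np.ndarray):
    """Remove the constant-function direction from a partition-of-unity basis.

    Column-centred spline bases still carry the all-ones coefficient direction
    in their null space (it maps to the zero function after centring), which
    also lies in the difference-penalty null space and would make the
    penalized system singular.  Reparameterize onto its orthogonal complement:
    returns (block @ Z, Z' S Z, Z).
    """
    from scipy.linalg import null_space

    k = block.shape[1]
    z = null_space(np.ones((1, k)))
    return block @ z, z.T @ penalty @ z, z


class ActivityTrendModel:
    """Quasi-binomial penalized-spline trend model for one activity x period.

    Parameters
    ----------
    data : DataFrame
        Long dataset from :func:`build_dataset` (or equivalent columns).
    activity, period : str
        Which slice of the dataset to model.
    include_individual_smooths : bool
        Add low-rank per-individual deviation smooths of days-since-laying,
        each with its own smoothing parameter (slower; off by default).
    n_knots : int
        Basis dimension of the group-level day smooths (default 12).
    moon_knots : int
        Basis dimension of the cyclic lunar smooth (default 3).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        activity: str = "foraging",
        period: str = "daylight",
        include_individual_smooths: bool = False,
        n_knots: int = 12,
        moon_knots: int = 3,
        deviation_rank: int = 5,
    ):
        d = data[(data["activity"] == activity) & (data["period"] == period)].copy()
        if d.empty:
            raise ValueError(f"no rows for activity={activity!r}, period={period!r}")
        statuses = sorted(d["status"].unique())
        for s in statuses:
            if d.loc[d["status"] == s, "individual_id"].nunique() < 2:
                raise ValueError(f"need at least two individuals with status {s!r}")
        self.data = d.reset_index(drop=True)
        self.activity, self.period = activity, period
        self.statuses = statuses
        self.birds = sorted(d["individual_id"].unique())
        self.n_knots, self.moon_knots = n_knots, moon_knots
        self.include_individual_smooths = include_individual_smooths
        self.deviation_rank = deviation_rank

        x = self.data["days_since_laying"].to_numpy(dtype=float)
        self.x_range = (float(x.min()), float(x.max()))
        self.y = self.data["proportion"].to_numpy(dtype=float)
        self.w = self.data["weight"].to_numpy(dtype=float)
        self._build_design()

    def _build_design(self) -> None:
        d = self.data
        n = len(d)
        x = d["days_since_laying"].to_numpy(dtype=float)
        cols = [np.ones((n, 1))]
        self.terms: list[_Term] = []
        pos = 1

        if len(self.statuses) > 1:
            for s in self.statuses[1:]:
                cols.append((d["status"] == s).to_numpy(dtype=float)[:, None])
            self.terms.append(
                _Term("status", slice(pos, pos + len(self.statuses) - 1), np.zeros((len(self.statuses) - 1,) * 2), 0.0, False)
            )
            pos += len(self.statuses) - 1

        basis = bspline_basis(x, self.n_knots, *self.x_range)
        self._day_colmeans = {}
        for s in self.statuses:
            ind = (d["status"] == s).to_numpy(dtype=float)
            mean_s = basis[ind > 0].mean(axis=0)
            self._day_colmeans[s] = mean_s
            block, pen, z = _absorb_constant(basis - mean_s, difference_penalty(self.n_knots))
            cols.append(block * ind[:, None])
            self.terms.append(
                _Term(f"f(days):{s}", slice(pos, pos + block.shape[1]), pen, transform=z)
            )
            pos += block.shape[1]

        mb = cyclic_basis(d["moon_age"].to_numpy(dtype=float), n_basis=self.moon_knots)
        self._moon_colmean = mb.mean(axis=0)
        block, pen, z = _absorb_constant(mb - self._moon_colmean, cyclic_penalty(self.moon_knots))
        cols.append(block)
        self.terms.append(_Term("f(moon)", slice(pos, pos + block.shape[1]), pen, transform=z))
        pos += block.shape[1]

        bird_idx = pd.Categorical(d["individual_id"], categories=self.birds).codes
        zb = np.zeros((n, len(self.birds)))
        zb[np.arange(n), bird_idx] = 1.0
        cols.append(zb)
        self.terms.append(_Term("bird", slice(pos, pos + len(self.birds)), np.eye(len(self.birds))))
        pos += len(self.birds)

        if self.include_individual_smooths:
            dev = bspline_basis(x, self.deviation_rank, *self.x_range)
            dev = dev - dev.mean(axis=0)
            pen = difference_penalty(self.deviation_rank, order=1) + 0.1 * np.eye(self.deviation_rank)
            for j, bird in enumerate(self.birds):
                ind = (bird_idx == j).astype(float)[:, None]
                cols.append(dev * ind)
                self.terms.append(_Term(f"g(days):{bird}", slice(pos, pos + self.deviation_rank), pen))
                pos += self.deviation_rank

        self.X = np.hstack(cols)
        self.p = self.X.shape[1]

    # -- fitting ------------------------------------------------------------

    def _penalty_total(self, lams: np.ndarray) -> np.ndarray:
        s = np.zeros((self.p, self.p))
        for t, lam in zip(self.terms, lams):
            if t.searchable:
                s[t.sl, t.sl] += lam * t.penalty
        return s

    def _pirls(self, lams: np.ndarray, max_iter: int = 60, tol: float = 1e-8):
        y, w, X = self.y, self.w, self.X
        n = len(y)
        s_total = self._penalty_total(lams) + 1e-10 * np.eye(self.p)
        mu = np.clip((y * w + 0.5) / (w + 1.0), _EPS, 1 - _EPS)
        eta = logit(mu)
        dev_old = np.inf
        beta = np.zeros(self.p)
        for _ in range(max_iter):
            v = mu * (1.0 - mu)
            wt = w * v
            if not np.all(np.isfinite(wt)) or wt.max() <= 0:
                raise ConvergenceError("degenerate IRLS weights (separation?)")
            z = eta + (y - mu) / v
            xw = X * wt[:, None]
            a = X.T @ xw + s_total
            try:
                c = cho_factor(a)
            except np.linalg.LinAlgError as e:  # pragma: no cover - defensive
                raise ConvergenceError(f"singular penalized system: {e}") from e
            beta = cho_solve(c, X.T @ (wt * z))
            eta = X @ beta
            mu = np.clip(expit(eta), _EPS, 1 - _EPS)
            dev = float(np.sum(w * (y - mu) ** 2 / (mu * (1 - mu))))
            if abs(dev - dev_old) < tol * (abs(dev) + 1e-12):
                break
            dev_old = dev
        else:
            raise ConvergenceError("PIRLS did not converge")
        xw = X * (w * mu * (1 - mu))[:, None]
        xtwx = X.T @ xw
        a = xtwx + s_total
        c = cho_factor(a)
        a_inv = cho_solve(c, np.eye(self.p))
        f_mat = a_inv @ xtwx
        edf_by_col = np.diag(f_mat)
        edf = float(edf_by_col.sum())
        pearson = float(np.sum(self.w * (y - mu) ** 2 / (mu * (1 - mu))))
        gcv = n * pearson / max(n - edf, 1.0) ** 2
        return {
            "beta": beta,
            "mu": mu,
            "eta": eta,
            "a_inv": a_inv,
            "edf_by_col": edf_by_col,
            "edf": edf,
            "pearson": pearson,
            "gcv": gcv,
        }

    def _gcv_search(self, n_grid: int = 7, n_golden: int = 10, passes: int = 2) -> np.ndarray:
        """Backfitting-style GCV optimization: per-term log-lambda line search."""
        lams = np.array([t.lam if t.searchable else 0.0 for t in self.terms])
        grid = np.logspace(-3, 5, n_grid)
        for _ in range(passes):
            for j, t in enumerate(self.terms):
                if not t.searchable:
                    continue
                scores = []
                for lam in grid:
                    trial = lams.copy()
                    trial[j] = lam
                    try:
                        scores.append(self._pirls(trial)["gcv"])
                    except ConvergenceError:
                        scores.append(np.inf)
                k = int(np.argmin(scores))
                lo = np.log(grid[max(k - 1, 0)])
                hi = np.log(grid[min(k + 1, n_grid - 1)])
                lams[j] = np.exp(self._golden(j, lams, lo, hi, n_golden))
        return lams

    def _golden(self, j: int, lams: np.ndarray, lo: float, hi: float, iters: int) -> float:
        phi = (np.sqrt(5.0) - 1.0) / 2.0

        def score(loglam: float) -> float:
            trial = lams.copy()
            trial[j] = np.exp(loglam)
            try:
                return self._pirls(trial)["gcv"]
            except ConvergenceError:
                return np.inf

        a, b = lo, hi
        c, d = b - phi * (b - a), a + phi * (b - a)
        fc, fd = score(c), score(d)
        for _ in range(iters):
            if fc < fd:
                b, d, fd = d, c, fc
                c = b - phi * (b - a)
                fc = score(c)
            else:
                a, c, fc = c, d, fd
                d = a + phi * (b - a)
                fd = score(d)
        return (a + b) / 2.0

    def fit(self, lambdas: dict | None = None) -> "ActivityTrendResults":
        """Fit by PIRLS, selecting smoothing parameters by GCV unless given.

        ``lambdas`` maps term names to fixed smoothing parameters; missing
        searchable terms are still optimized.
        """
        if lambdas is not None:
            fixed = np.array(
                [lambdas.get(t.name, t.lam) if t.searchable else 0.0 for t in self.terms]
            )
            if all(t.name in lambdas for t in self.terms if t.searchable):
                lams = fixed
            else:
                for t, lam in zip(self.terms, fixed):
                    t.lam = lam
                lams = self._gcv_search()
        else:
            lams = self._gcv_search()
        sol = self._pirls(lams)
        n = len(self.y)
        dispersion = sol["pearson"] / max(n - sol["edf"], 1.0)
        return ActivityTrendResults(model=self, lams=lams, dispersion=float(dispersion), **sol)


class ActivityTrendResults:
    """Fitted penalized quasi-binomial trend model."""

    def __init__(self, model, lams, beta, mu, eta, a_inv, edf_by_col, edf, pearson, gcv, dispersion):
        self.model = model
        self.lams = lams
        self.params = beta
        self.fittedvalues = mu
        self.eta = eta
        self._a_inv = a_inv
        self.edf_by_col = edf_by_col
        self.edf = edf
        self.pearson_chi2 = pearson
        self.gcv = gcv
        self.dispersion = dispersion
        #: penalized ("Bayesian") coefficient covariance, scaled by dispersion
        self.cov_params = dispersion * a_inv

    # -- accessors ----------------------------------------------------------

    def term_edf(self) -> dict[str, float]:
        return {
            t.name: float(self.edf_by_col[t.sl].sum()) for t in self.model.terms
        }

    def _term(self, name: str) -> _Term:
        for t in self.model.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def predict_group_curve(self, status: str, days: np.ndarray, ci: bool = True) -> pd.DataFrame:
        """Group-level trend on the proportion scale at lunar-average moon effect.

        Linear predictor = intercept + status effect + centred day smooth for
        the group; pointwise 95% CI from the penalized covariance.
        """
        m = self.model
        days = np.asarray(days, dtype=float)
        xp = np.zeros((len(days), m.p))
        xp[:, 0] = 1.0
        if len(m.statuses) > 1 and status != m.statuses[0]:
            st = self._term("status")
            xp[:, st.sl.start + m.statuses[1:].index(status)] = 1.0
        t = self._term(f"f(days):{status}")
        basis = bspline_basis(days, m.n_knots, *m.x_range)
        xp[:, t.sl] = (basis - m._day_colmeans[status]) @ t.transform
        eta = xp @ self.params
        out = pd.DataFrame({"days_since_laying": days, "estimate": expit(eta)})
        if ci:
            se = np.sqrt(np.einsum("ij,jk,ik->i", xp, self.cov_params, xp))
            out["lo"] = expit(eta - 1.96 * se)
            out["hi"] = expit(eta + 1.96 * se)
        return out

    def predict_moon_curve(self, moon_age: np.ndarray, ci: bool = True) -> pd.DataFrame:
        """Cyclic lunar partial effect (logit scale, centred) with pointwise CI."""
        m = self.model
        t = self._term("f(moon)")
        xb = (cyclic_basis(np.asarray(moon_age, dtype=float), n_basis=m.moon_knots) - m._moon_colmean) @ t.transform
        eff = xb @ self.params[t.sl]
        out = pd.DataFrame({"moon_age": moon_age, "effect": eff})
        if ci:
            v = self.cov_params[t.sl, t.sl]
            se = np.sqrt(np.einsum("ij,jk,ik->i", xb, v, xb))
            out["lo"] = eff - 1.96 * se
            out["hi"] = eff + 1.96 * se
        return out

    def test_smooth_terms(self) -> pd.DataFrame:
        """Wald-type F statistics for each penalized smooth term.

        For term j: F = beta_j' V_jj^- beta_j / edf_j with the penalized
        covariance and rank from the rounded edf; the reference distribution is
        F(edf_j, n - total edf).  Approximate, as for any penalized fit.
        """
        n = len(self.model.y)
        df_resid = max(n - self.edf, 1.0)
        rows = []
        for t in self.model.terms:
            if not t.searchable or t.name == "bird" or t.name.startswith("g(days)"):
                continue
            b = self.params[t.sl]
            v = self.cov_params[t.sl, t.sl]
            edf_t = float(self.edf_by_col[t.sl].sum())
            rank = max(int(round(edf_t)), 1)
            evals, evecs = np.linalg.eigh(v)
            order = np.argsort(evals)[::-1]
            evals, evecs = evals[order[:rank]], evecs[:, order[:rank]]
            if np.any(evals <= 0):
                raise np.linalg.LinAlgError("singular term covariance")
            proj = evecs.T @ b
            wald = float(proj @ (proj / evals))
            fstat = wald / rank
            p = float(stats.f.sf(fstat, rank, df_resid))
            rows.append(
                {"term": t.name, "edf": edf_t, "ref_df": t.penalty.shape[0], "F": fstat, "p_value": p}
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Quasi-binomial penalized-smooth trend: {m.activity} / {m.period}",
            "-" * 64,
            f"observations        {len(m.y):>10d}",
            f"individuals         {len(m.birds):>10d}",
            f"total edf           {self.edf:>10.2f}",
            f"dispersion (Pearson){self.dispersion:>10.3f}",
            f"GCV score           {self.gcv:>10.4f}",
            "",
            f"{'term':<22s}{'edf':>8s}{'lambda':>12s}",
        ]
        for t, lam in zip(m.terms, self.lams):
            edf_t = float(self.edf_by_col[t.sl].sum())
            lines.append(f"{t.name:<22s}{edf_t:>8.2f}{(lam if t.searchable else 0):>12.3g}")
        tests = self.test_smooth_terms()
        lines.append("")
        lines.append(f"{'smooth term':<22s}{'edf':>8s}{'F':>10s}{'p':>10s}")
        for _, r in tests.iterrows():
            lines.append(f"{r['term']:<22s}{r['edf']:>8.2f}{r['F']:>10.2f}{r['p_value']:>10.3g}")
        return "\n".join(lines)


def fit_trend_model(
    data: pd.DataFrame,
    activity: str,
    period: str,
    include_individual_smooths: bool = False,
    **kw,
) -> ActivityTrendResults:
    """Convenience wrapper: build and fit an :class:`ActivityTrendModel`."""
    return ActivityTrendModel(
        data, activity=activity, period=period, include_individual_smooths=include_individual_smooths, **kw
    ).fit()


# ---------------------------------------------------------------------------
# Moon-cycle window comparison
# ---------------------------------------------------------------------------


def window_comparison(
    budgets: pd.DataFrame,
    records,
    window_a: tuple = (np.datetime64("2013-01-28"), np.datetime64("2013-02-25")),
    window_b: tuple = (np.datetime64("2013-06-24"), np.datetime64("2013-07-21")),
    n_iter: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare activity budgets between two one-lunar-cycle windows.

    Defaults are the early chick-rearing (28 Jan – 25 Feb 2013) and
    nonbreeding (24 Jun – 21 Jul 2013) windows.  Per-individual mean
    proportions within each window are the analysis unit: the summary table
    gives group means ± SD by status x sex x period x window, and the test
    table reports bootstrap/permutation comparisons for the window factor
    (paired within individual, sign-flip permutation) and for status and sex
    within each window.
    """
    meta = {r.individual_id: (r.status, r.sex) for r in records}
    b = budgets[budgets["individual_id"].isin(meta) & (budgets["atsea_min"] > 0)].copy()
    b["date"] = pd.to_datetime(b["date"])
    frames = []
    for wname, (lo, hi) in (("a", window_a), ("b", window_b)):
        sel = b[(b["date"] >= pd.Timestamp(lo)) & (b["date"] <= pd.Timestamp(hi))]
        if sel.empty:
            raise ValueError(f"window {wname} contains no budget rows")
        g = (
            sel.groupby(["individual_id", "period"])[["prop_foraging", "prop_flight", "prop_float"]]
            .mean()
            .reset_index()
        )
        g["window"] = wname
        frames.append(g)
    per_ind = pd.concat(frames, ignore_index=True)
    per_ind["status"] = per_ind["individual_id"].map(lambda i: meta[i][0])
    per_ind["sex"] = per_ind["individual_id"].map(lambda i: meta[i][1])

    summary = (
        per_ind.groupby(["window", "period", "status", "sex"])[["prop_foraging", "prop_flight", "prop_float"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    summary.columns = ["_".join(c).rstrip("_") for c in summary.columns]

    rng = np.random.default_rng(seed)
    tests = []
    for act_col in ("prop_foraging", "prop_flight", "prop_float"):
        for period in per_ind["period"].unique():
            sub = per_ind[per_ind["period"] == period]
            # window factor: paired within individual, sign-flip permutation
            wide = sub.pivot_table(index="individual_id", columns="window", values=act_col)
            wide = wide.dropna()
            if {"a", "b"} <= set(wide.columns) and len(wide) >= 2:
                diff = (wide["a"] - wide["b"]).to_numpy()
                obs = float(diff.mean())
                signs = rng.choice([-1.0, 1.0], size=(n_iter, len(diff)))
                null = (signs * diff).mean(axis=1)
                p = float((np.sum(np.abs(null) >= abs(obs)) + 1) / (n_iter + 1))
                tests.append(
                    {"activity": act_col, "period": period, "factor": "window", "difference": obs, "p": p}
                )
            # status and sex within each window
            for factor in ("status", "sex"):
                for wname in ("a", "b"):
                    ws = sub[sub["window"] == wname]
                    if ws[factor].nunique() == 2 and ws.groupby(factor)[act_col].count().min() >= 2:
                        res = bootstrap_group_difference(
                            ws[act_col], ws[factor], n_iter=n_iter, seed=int(rng.integers(2**31 - 1))
                        )
                        tests.append(
                            {
                                "activity": act_col,
                                "period": period,
                                "factor": f"{factor}[{wname}]",
                                "difference": res["difference"],
                                "p": res["p_permutation"],
                            }
                        )
    return summary, pd.DataFrame(tests)
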