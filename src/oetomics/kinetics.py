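"""Mass-action kinetic model of protein dynamics.

Protein abundance p(t) is driven by translation (RPF level r(t)) and
first-order degradation:

    dp/dt = alpha * r(t) - kd * p(t),    p(t_1) = p0

with gene-specific, time-constant synthesis efficiency ``alpha`` and
degradation rate ``kd`` (both >= 0).  r(t) is only measured at the stage
time points, so it is linearly interpolated between them; within each
segment the ODE then has a closed-form solution (integrating factor with
linear forcing), which is what :func:`simulate_protein` evaluates.

Two fitting variants are supported:

``p0_rpf``
    p0 is pinned to the observed first-stage (FGO) protein level; the free
    parameters (alpha, kd) are chosen to minimize the sum of squared
    differences between predicted and observed protein over the observed
    stages.
``rpf_only``
    identical, except p0 is forced to 0 — the model must build the protein
    from translation alone.  Comparing the two isolates the contribution of
    the maternal protein stockpile.

Fitting exploits that the solution is linear in (p0, alpha) for fixed kd:
p(t_i) = p0 * D_i(kd) + alpha * S_i(kd), so the optimal nonnegative alpha
has a closed form per kd.  The optimizer profiles alpha over a dense
log-spaced kd grid and polishes the best candidates with bounded L-BFGS-B
in (alpha, kd) jointly; the procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import spearmanr

from .errors import FitError, InputError

__all__ = [
    "RpfTrajectory",
    "KineticFit",
    "interpolate_rpf",
    "simulate_protein",
    "fit_kinetic_model",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class RpfTrajectory:
    """Piecewise-linear translation input: r(t_k) at strictly increasing nodes."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or t.size < 2:
            raise InputError("trajectory needs at least two time points")
        if v.shape != t.shape:
            raise InputError("times and values must have equal length")
        if np.any(np.diff(t) <= 0):
            raise InputError("trajectory times must be strictly increasing")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise InputError("RPF values must be finite and nonnegative")


def interpolate_rpf(traj: RpfTrajectory, t: float | np.ndarray) -> float | np.ndarray:
    """Linearly interpolated r(t); exact at the nodes, error outside the range."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < traj.times[0]) or np.any(t_arr > traj.times[-1]):
        raise InputError(
            f"time outside trajectory range [{traj.times[0]}, {traj.times[-1]}]"
        )
    out = np.interp(t_arr, traj.times, traj.values)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


# -- closed-form segment propagation --------------------------------------

def _phi1(x: np.ndarray) -> np.ndarray:
    """(1 - exp(-x)) / x, series near 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)
    out = -np.expm1(-xs) / xs
    series = 1.0 - x / 2.0 + x * x / 6.0 - x ** 3 / 24.0
    return np.where(small, series, out)


def _phi2(x: np.ndarray) -> np.ndarray:
    """(x - 1 + exp(-x)) / x^2, series near 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)
    out = (xs - 1.0 + np.exp(-xs)) / (xs * xs)
    series = 0.5 - x / 6.0 + x * x / 24.0 - x ** 3 / 120.0
    return np.where(small, series, out)


def _segment_advance(p_start, tau, r_start, slope, alpha, kd):
    """Propagate p across tau within one linear-forcing segment.

    r(s) = r_start + slope * s for s in [0, tau];
    p(tau) = p_start e^{-kd tau}
             + alpha [ r_start tau phi1(kd tau) + slope tau^2 phi2(kd tau) ].
    """
    x = kd * tau
    return (
        p_start * np.exp(-x)
        + alpha * (r_start * tau * _phi1(x) + slope * tau * tau * _phi2(x))
    )


def simulate_protein(
    p0: float,
    alpha: float,
    kd: float,
    traj: RpfTrajectory,
    eval_times: np.ndarray | None = None,
) -> np.ndarray:
    """Solve the kinetic ODE exactly on the piecewise-linear forcing.

    Parameters are on linear abundance scale; ``eval_times`` defaults to the
    trajectory nodes and must lie inside the trajectory range.
    """
    if p0 < 0 or alpha < 0 or kd < 0:
        raise InputError("p0, alpha and kd must be nonnegative")
    t_nodes = traj.times
    r_nodes = traj.values
    if eval_times is None:
        eval_times = t_nodes
    eval_times = np.asarray(eval_times, dtype=float)
    if np.any(eval_times < t_nodes[0]) or np.any(eval_times > t_nodes[-1]):
        raise InputError("eval_times outside trajectory range")

    # march over segments, recording p at segment starts
    p_at_node = np.empty_like(t_nodes)
    p_at_node[0] = p0
    slopes = np.diff(r_nodes) / np.diff(t_nodes)
    for k in range(len(t_nodes) - 1):
        p_at_node[k + 1] = _segment_advance(
            p_at_node[k], t_nodes[k + 1] - t_nodes[k], r_nodes[k], slopes[k], alpha, kd
        )

    seg = np.clip(np.searchsorted(t_nodes, eval_times, side="right") - 1, 0, len(t_nodes) - 2)
    tau = eval_times - t_nodes[seg]
    return _segment_advance(p_at_node[seg], tau, r_nodes[seg], slopes[seg], alpha, kd)


# -- fitting ---------------------------------------------------------------

@dataclass
class KineticFit:
    """Per-gene fit result (linear abundance scale)."""

    gene_id: str
    mode: str
    p0: float
    alpha: float
    kd: float
    predicted: np.ndarray = field(repr=False)
    sse: float = np.nan
    r_pred_obs: float = np.nan
    boundary_flag: bool = False
    eval_times: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def _node_response(kd: np.ndarray, traj: RpfTrajectory) -> np.ndarray:
    """Unit-alpha synthesis response at the trajectory nodes.

    Vectorized over kd: returns an (n_kd, n_nodes) array of the solution
    with p0 = 0, alpha = 1 for each degradation rate.
    """
    kd = np.atleast_1d(np.asarray(kd, dtype=float))
    t, r = traj.times, traj.values
    slopes = np.diff(r) / np.diff(t)
    resp = np.zeros((kd.size, t.size))
    for k in range(t.size - 1):
        resp[:, k + 1] = _segment_advance(
            resp[:, k], t[k + 1] - t[k], r[k], slopes[k], 1.0, kd
        )
    return resp


def _profile_alpha_grid(p0, kd, traj, keep, obs_values):
    """Optimal nonnegative alpha and SSE for each kd in a grid."""
    kd = np.atleast_1d(np.asarray(kd, dtype=float))
    obs_times = traj.times[keep]
    s = _node_response(kd, traj)[:, keep]                      # (n_kd, n_obs)
    d = p0 * np.exp(-np.outer(kd, obs_times - traj.times[0]))  # (n_kd, n_obs)
    resid0 = obs_values[None, :] - d
    ss = np.einsum("ij,ij->i", s, s)
    num = np.einsum("ij,ij->i", s, resid0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(ss > 0, np.maximum(0.0, num / np.where(ss > 0, ss, 1.0)), 0.0)
    r = resid0 - alpha[:, None] * s
    sse = np.einsum("ij,ij->i", r, r)
    return alpha, sse


def fit_kinetic_model(
    observed: np.ndarray | pd.Series,
    traj: RpfTrajectory,
    mode: str = "p0_rpf",
    gene_id: str = "",
    kd_grid: np.ndarray | None = None,
    n_polish: int = 3,
    upper_bound: float = 1e6,
) -> KineticFit:
    """Fit (alpha, kd) by bounded least squares on linear protein abundance.

    ``observed`` gives per-stage protein values aligned with ``traj.times``;
    NaN entries (not detected) are dropped from the objective.  In
    ``p0_rpf`` mode p0 is the observed value at the first trajectory time
    point (0 if not observed there); in ``rpf_only`` mode p0 = 0.
    """
    if mode not in ("p0_rpf", "rpf_only"):
        raise InputError(f"unknown mode: {mode!r}")
    obs = np.asarray(observed, dtype=float)
    if obs.shape != traj.times.shape:
        raise InputError("observed values must align with trajectory time points")
    keep = np.isfinite(obs)
    if keep.sum() == 0:
        raise FitError(f"gene {gene_id!r}: no observed stages")
    if keep.sum() < 3:
        raise FitError(f"gene {gene_id!r}: fewer than 3 observed stages")
    obs_times = traj.times[keep]
    obs_values = obs[keep]
    if not np.all(np.isfinite(obs_values)):
        raise FitError(f"gene {gene_id!r}: non-finite observations")

    if mode == "p0_rpf":
        p0 = float(obs[0]) if np.isfinite(obs[0]) and obs[0] > 0 else 0.0
    else:
        p0 = 0.0

    t_span = traj.times[-1] - traj.times[0]
    if kd_grid is None:
        kd_grid = np.concatenate([[0.0], np.geomspace(1e-4, 50.0, 50) / t_span * 6.0])
    kd_grid = np.asarray(kd_grid, dtype=float)

    # profile alpha (closed-form nonnegative LS) over the kd grid
    alphas, sses = _profile_alpha_grid(p0, kd_grid, traj, keep, obs_values)
    if not np.any(np.isfinite(sses)):
        raise FitError(f"gene {gene_id!r}: non-finite objective")
    order = np.argsort(sses)

    def profile_sse(kd: float) -> float:
        _, sse = _profile_alpha_grid(p0, np.array([kd]), traj, keep, obs_values)
        return float(sse[0])

    # bracketed 1-D refinement around the best grid points
    best = None
    for idx in order[:n_polish]:
        lo = kd_grid[idx - 1] if idx > 0 else 0.0
        hi = kd_grid[idx + 1] if idx + 1 < len(kd_grid) else kd_grid[idx] * 4 + 1e-6
        res = optimize.minimize_scalar(
            profile_sse, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        cand = (float(res.x), float(res.fun))
        if best is None or cand[1] < best[1]:
            best = cand
        if sses[idx] < best[1]:
            best = (float(kd_grid[idx]), float(sses[idx]))

    # joint (alpha, kd) polish with bounded quasi-Newton
    scale = max(float(np.max(obs_values)), 1.0)
    bounds = [(0.0, upper_bound * scale), (0.0, upper_bound)]
    alpha_b, _ = _profile_alpha_grid(p0, np.array([best[0]]), traj, keep, obs_values)

    def objective(theta):
        a, k = theta
        s = _node_response(np.array([k]), traj)[0, keep]
        pred = p0 * np.exp(-k * (obs_times - traj.times[0])) + a * s
        r = pred - obs_values
        return float(np.dot(r, r))

    res2 = optimize.minimize(
        objective,
        x0=np.array([alpha_b[0], best[0]]),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 100, "ftol": 1e-15, "gtol": 1e-13},
    )
    kd_hat, sse = best
    if np.isfinite(res2.fun) and res2.fun < sse:
        kd_hat, sse = float(res2.x[1]), float(res2.fun)
    # exact 1-D optimum in alpha at the final kd
    alpha_arr, sse_arr = _profile_alpha_grid(p0, np.array([kd_hat]), traj, keep, obs_values)
    alpha_hat, sse = float(alpha_arr[0]), float(sse_arr[0])
    predicted = simulate_protein(p0, alpha_hat, kd_hat, traj, traj.times)
    r_po = _safe_spearman(predicted[keep], obs_values)
    at_bound = alpha_hat >= bounds[0][1] * (1 - 1e-9) or kd_hat >= bounds[1][1] * (1 - 1e-9)
    return KineticFit(
        gene_id=gene_id,
        mode=mode,
        p0=p0,
        alpha=float(alpha_hat),
        kd=float(kd_hat),
        predicted=predicted,
        sse=float(sse),
        r_pred_obs=r_po,
        boundary_flag=bool(at_bound),
        eval_times=traj.times,
    )


def _safe_spearman(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    return float(spearmanr(a, b).statistic)


def evaluate_predictions(fits: list[KineticFit], observed: pd.DataFrame) -> dict:
    """Summarize prediction quality: per-gene Spearman(pred, obs) and medians.

    ``observed`` is a stage-averaged gene x stage frame on the same linear
    scale as the fits.  Genes whose predicted series is constant (rank
    correlation undefined) are excluded from the median and counted.
    """
    rows = []
    n_excluded = 0
    for fit in fits:
        if fit.gene_id not in observed.index:
            continue
        obs = observed.loc[fit.gene_id].to_numpy(dtype=float)
        keep = np.isfinite(obs)
        r = _safe_spearman(fit.predicted[keep], obs[keep]) if keep.sum() >= 3 else np.nan
        if np.isnan(r):
            n_excluded += 1
        rows.append({"gene_id": fit.gene_id, "mode": fit.mode, "r_pred_obs": r})
    table = pd.DataFrame(rows)
    medians = (
        table.dropna(subset=["r_pred_obs"]).groupby("mode")["r_pred_obs"].median().to_dict()
        if len(table)
        else {}
    )
    return {"per_gene": table, "median_by_mode": medians, "n_excluded": n_excluded}


def fit_matrix(
    protein,
    rpf,
    mode: str = "p0_rpf",
    genes=None,
) -> tuple[list[KineticFit], int]:
    """Fit the kinetic model for every gene of a stage-averaged bundle.

    ``protein`` holds log2 intensities (converted to linear scale for the
    mass-action balance); ``rpf`` holds FPKM values used as the piecewise-
    linear forcing.  Genes with fewer than three observed protein stages
    are skipped.  Returns (fits, number skipped).
    """
    from .errors import InputError
    from .matrix import OmicsMatrix  # noqa: F401  (documentation of expected type)

    if not (protein.is_stage_averaged and rpf.is_stage_averaged):
        raise InputError("fit_matrix expects stage-averaged matrices")
    stages = [s for s in protein.values.columns if s in set(rpf.values.columns)]
    times = np.array([protein.series.time_of(s) for s in stages])
    if genes is None:
        genes = protein.genes.intersection(rpf.genes)
    linear = 2.0 ** protein.values.loc[genes, stages]
    forcing = rpf.values.loc[genes, stages].fillna(0.0)
    fits: list[KineticFit] = []
    n_skipped = 0
    for g in genes:
        obs = linear.loc[g].to_numpy(dtype=float)
        if np.isfinite(obs).sum() < 3:
            n_skipped += 1
            continue
        traj = RpfTrajectory(times, forcing.loc[g].to_numpy(dtype=float))
        try:
            fits.append(fit_kinetic_model(obs, traj, mode=mode, gene_id=str(g)))
        except FitError:
            n_skipped += 1
    return fits, n_skipped


def fits_to_frame(fits: list[KineticFit]) -> pd.DataFrame:
    """Tabulate a list of fits (gene, p0, alpha, kd, sse, r_pred_obs, boundary_flag)."""
    return pd.DataFrame(
        {
            "gene_id": [f.gene_id for f in fits],
            "mode": [f.mode for f in fits],
            "p0": [f.p0 for f in fits],
            "alpha": [f.alpha for f in fits],
            "kd": [f.kd for f in fits],
            "sse": [f.sse for f in fits],
            "r_pred_obs": [f.r_pred_obs for f in fits],
            "boundary_flag": [f.boundary_flag for f in fits],
        }
    ).set_index("gene_id")
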