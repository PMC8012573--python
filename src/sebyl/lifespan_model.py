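"""Pooled-screen replicative-lifespan estimation from barcode counts.

The estimator turns strain fractions measured across successive rounds of
old-mother-cell sorting into per-strain survival curves and fits a modified
Gompertz model::

    S(G) = a * exp(-b * c**G),   a = 1 (100%), b > 0, c > 1

where ``G`` is the cumulative number of generations. Survival at sorting
round ``n`` follows the recurrence

    S_n = S_{n-1} * (Fo_n * To_n) / (Fo_{n-1} * To_{n-1} * r_n)

with ``Fo`` the strain's fraction of the mother pool (from barcode counts),
``To`` the microscope-counted mother-pool total, and ``r_n`` the magnetic-bead
recovery rate. Generations per round come from the daughter (young) pool:

    G_n = log2(Fy_n / Fy_{n-1}) + log2(Ty_n / To_{n-1})

The unsorted starting culture provides the round-0 baseline for both mother
and daughter fractions (Fy_0 = USC fraction, Ty_0 = To_0). Median lifespan is
the generation count where fitted survival crosses 50%; each mutant is
compared to a wild-type reference with an extra-sum-of-squares F-test, and
strains more than one sample standard deviation above/below the mean score
are classified long/short lived.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .barcode_decode import CountTable

__all__ = [
    "Classification",
    "FitStatus",
    "GompertzFit",
    "ScreenConfig",
    "ScreenReplicate",
    "SortMetadata",
    "StrainTrajectory",
    "TagPolicy",
    "classify_strains",
    "compute_fractions",
    "compute_generations",
    "compute_survival",
    "estimate_recovery_rate",
    "f_test_vs_wildtype",
    "fit_gompertz",
    "gompertz_survival",
    "median_lifespan",
    "run_screen",
]

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# metadata and configuration
# ---------------------------------------------------------------------------

@dataclass
class SortMetadata:
    """Per-replicate sorting metadata.

    Attributes
    ----------
    To : array, length N+1
        Mother-pool total cell counts; ``To[0]`` is the unsorted total.
    Ty : array, length N+1
        Daughter-pool totals; ``Ty[0] := To[0]`` (no round-0 daughter sample).
    r : array, length N
        Bead recovery rate per sorting round, each in (0, 1].
    roles : mapping sample_id -> (role, round)
        role in {"unsorted", "young", "old"}; round 0 for unsorted, 1..N else.
    """

    To: np.ndarray
    Ty: np.ndarray
    r: np.ndarray
    roles: dict[str, Tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.To = np.asarray(self.To, dtype=float)
        self.Ty = np.asarray(self.Ty, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        n = self.rounds
        if n < 1:
            raise ValueError("need at least one sorting round")
        if self.To.shape != (n + 1,) or self.Ty.shape != (n + 1,):
            raise ValueError("To and Ty must have length rounds + 1")
        if np.any(self.To <= 0) or np.any(self.Ty <= 0):
            raise ValueError("cell totals must be positive")
        if np.any(self.r <= 0) or np.any(self.r > 1):
            raise ValueError("recovery rates must lie in (0, 1]")

    @property
    def rounds(self) -> int:
        return len(self.r)

    def sample_for(self, role: str, rnd: int) -> str:
        for sid, (ro, rn) in self.roles.items():
            if ro == role and rn == rnd:
                return sid
        raise KeyError(f"no sample with role={role!r} round={rnd}")


class TagPolicy(str, enum.Enum):
    UPTAG_ONLY = "uptag_only"
    DNTAG_ONLY = "dntag_only"
    MEAN_OF_TAGS = "mean_of_tags"


@dataclass
class ScreenConfig:
    """Tunable parameters of the screen analysis."""

    pseudocount: float = 0.5
    tag_policy: TagPolicy = TagPolicy.MEAN_OF_TAGS
    min_usc_count: int = 20          # strains below this in any replicate are excluded
    rounds_used: Optional[int] = None  # fit on first k rounds only; None = all
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        self.tag_policy = TagPolicy(self.tag_policy)


@dataclass
class ScreenReplicate:
    """One biological replicate: the two count tables plus sort metadata."""

    counts_up: CountTable
    counts_dn: CountTable
    meta: SortMetadata


# ---------------------------------------------------------------------------
# fractions, survival and generations (the per-strain trajectory)
# ---------------------------------------------------------------------------

def _sample_fractions(table: CountTable, pseudocount: float) -> pd.DataFrame:
    c = table.to_frame().astype(float) + pseudocount
    return c / c.sum(axis=0)


def compute_fractions(
    counts_up: Optional[CountTable],
    counts_dn: Optional[CountTable],
    meta: SortMetadata,
    pseudocount: float = 0.5,
    tag_policy: TagPolicy = TagPolicy.MEAN_OF_TAGS,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-strain mother (Fo) and daughter (Fy) fractions by round.

    Fraction of strain i in sample s is ``(count_is + pseudocount) /
    sum_j (count_js + pseudocount)``; under ``mean_of_tags`` the UPTAG and
    DNTAG fractions are computed separately and then averaged, so each
    sample's fractions still sum to 1.

    Returns two DataFrames (strains x rounds 0..N): ``Fo`` with round 0 the
    unsorted sample and rounds 1..N the old fractions, and ``Fy`` with round 0
    the unsorted sample and rounds 1..N the young fractions.
    """
    tag_policy = TagPolicy(tag_policy)
    parts = []
    if tag_policy in (TagPolicy.UPTAG_ONLY, TagPolicy.MEAN_OF_TAGS):
        if counts_up is None:
            raise ValueError("tag policy requires UPTAG counts")
        parts.append(_sample_fractions(counts_up, pseudocount))
    if tag_policy in (TagPolicy.DNTAG_ONLY, TagPolicy.MEAN_OF_TAGS):
        if counts_dn is None:
            raise ValueError("tag policy requires DNTAG counts")
        parts.append(_sample_fractions(counts_dn, pseudocount))
    frac = parts[0] if len(parts) == 1 else (parts[0] + parts[1]) / 2.0

    n = meta.rounds
    for sid in frac.columns:
        if sid not in meta.roles:
            raise ValueError(f"sample {sid!r} has no role mapping")
    usc = meta.sample_for("unsorted", 0)
    fo = pd.DataFrame(index=frac.index, columns=range(n + 1), dtype=float)
    fy = fo.copy()
    fo[0] = frac[usc]
    fy[0] = frac[usc]
    for k in range(1, n + 1):
        fo[k] = frac[meta.sample_for("old", k)]
        fy[k] = frac[meta.sample_for("young", k)]
    return fo, fy


def compute_survival(fo: np.ndarray, meta: SortMetadata) -> np.ndarray:
    """Survival S_n for one strain from its mother-pool fractions.

    ``S[0] = 1``; values above 1 (apparent enrichment beyond baseline) are
    retained, not clipped. A zero fraction at step n-1 makes survival
    undefined (NaN) from step n onward.
    """
    fo = np.asarray(fo, dtype=float)
    n = meta.rounds
    s = np.full(n + 1, np.nan)
    s[0] = 1.0
    for k in range(1, n + 1):
        if not np.isfinite(s[k - 1]) or fo[k - 1] <= 0:
            break
        s[k] = s[k - 1] * (fo[k] * meta.To[k]) / (fo[k - 1] * meta.To[k - 1] * meta.r[k - 1])
    return s


def compute_generations(fy: np.ndarray, meta: SortMetadata) -> Tuple[np.ndarray, np.ndarray]:
    """Per-round (Gstep) and cumulative (Gcum) generations for one strain.

    ``Gcum[0] = 0``; a non-positive daughter fraction leaves later steps NaN.
    """
    fy = np.asarray(fy, dtype=float)
    n = meta.rounds
    gstep = np.full(n, np.nan)
    for k in range(1, n + 1):
        if fy[k - 1] <= 0 or fy[k] <= 0:
            break
        gstep[k - 1] = (np.log2(fy[k] / fy[k - 1])
                        + np.log2(meta.Ty[k] / meta.To[k - 1]))
    gcum = np.concatenate([[0.0], np.cumsum(gstep)])
    return gstep, gcum


@dataclass
class StrainTrajectory:
    """Full per-strain trajectory: fractions, survival, generations."""

    strain_id: str
    Fo: np.ndarray
    Fy: np.ndarray
    S: np.ndarray
    Gstep: np.ndarray
    Gcum: np.ndarray

    @classmethod
    def from_fractions(cls, strain_id: str, fo: np.ndarray, fy: np.ndarray,
                       meta: SortMetadata) -> "StrainTrajectory":
        s = compute_survival(fo, meta)
        gstep, gcum = compute_generations(fy, meta)
        return cls(strain_id, np.asarray(fo, float), np.asarray(fy, float),
                   s, gstep, gcum)

    def fit_points(self, rounds_used: Optional[int] = None) -> Tuple[np.ndarray, np.ndarray]:
        """(G, S) pairs usable for fitting: both finite, from round 0 up."""
        upto = len(self.S) if rounds_used is None else rounds_used + 1
        g, s = self.Gcum[:upto], self.S[:upto]
        ok = np.isfinite(g) & np.isfinite(s)
        return g[ok], s[ok]


# ---------------------------------------------------------------------------
# Gompertz fitting
# ---------------------------------------------------------------------------

class FitStatus(str, enum.Enum):
    OK = "ok"
    FAILED = "failed"
    DEGENERATE = "degenerate"


@dataclass
class GompertzFit:
    """Result of fitting S = a*exp(-b*c^G) with a fixed at 1."""

    b: float
    c: float
    rss: float
    n_points: int
    status: FitStatus
    a: float = 1.0
    median_G: float = float("nan")
    left_censored: bool = False


def gompertz_survival(g, b: float, c: float, a: float = 1.0):
    """Evaluate S(G) = a * exp(-b * c**G), overflow-safe."""
    g = np.asarray(g, dtype=float)
    t = np.clip(math.log(b) + g * math.log(c), -745.0, 700.0)
    return a * np.exp(-np.exp(t))


def _loglog_init(g: np.ndarray, s: np.ndarray) -> Tuple[float, float]:
    """Initial (b, c) from the linearization ln(-ln S) = ln b + G ln c,
    ordinary least squares over points with 0 < S < 1."""
    ok = (s > 0) & (s < 1)
    if ok.sum() >= 2 and np.ptp(g[ok]) > 0:
        y = np.log(-np.log(s[ok]))
        slope, intercept = np.polyfit(g[ok], y, 1)
        if slope > 1e-9 and np.isfinite(intercept):
            return float(np.exp(intercept)), float(np.exp(slope))
    return 0.05, 1.1


def fit_gompertz(g: Sequence[float], s: Sequence[float],
                 include_origin: bool = True) -> GompertzFit:
    """Nonlinear least squares fit of the modified Gompertz model.

    Minimizes ``sum (S_i - exp(-b*c^{G_i}))^2`` over b > 0, c > 1 with the
    survival ceiling fixed at a = 1. The constraints are enforced by
    optimizing over (log b, log(c-1)); the starting point comes from the
    log-log linearization. With ``include_origin`` the (G=0, S=1) anchor is
    added when not already present.

    Raises ``ValueError`` with fewer than 3 points. Returns status
    ``degenerate`` when there is no mortality signal (all S at the ceiling)
    or when the optimum collapses onto a parameter bound, ``failed`` on
    non-convergence.
    """
    g = np.asarray(g, dtype=float)
    s = np.asarray(s, dtype=float)
    if g.shape != s.shape or g.ndim != 1:
        raise ValueError("g and s must be 1-D arrays of equal length")
    if include_origin and not np.any(g == 0.0):
        g = np.concatenate([[0.0], g])
        s = np.concatenate([[1.0], s])
    if len(g) < 3:
        raise ValueError("need at least 3 points to fit")
    if not np.all(np.isfinite(g)) or not np.all(np.isfinite(s)) or np.any(s < 0):
        raise ValueError("points must be finite with S >= 0")

    if np.allclose(s, 1.0, atol=1e-9):
        return GompertzFit(math.nan, math.nan, 0.0, len(g), FitStatus.DEGENERATE)

    b0, c0 = _loglog_init(g, s)

    def resid(theta: np.ndarray) -> np.ndarray:
        log_b, log_cm1 = theta
        c = 1.0 + math.exp(log_cm1)
        t = np.clip(log_b + g * math.log(c), -745.0, 700.0)
        return s - np.exp(-np.exp(t))

    starts = [(b0, c0), (0.01, 1.05), (0.1, 1.2), (0.3, 1.5), (1e-3, 1.1)]
    best = None
    for bb, cc in starts:
        theta0 = np.array([math.log(bb), math.log(max(cc - 1.0, 1e-6))])
        try:
            res = optimize.least_squares(resid, theta0, method="lm",
                                         xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                         max_nfev=20000)
        except Exception:
            continue
        if res.success and np.all(np.isfinite(res.x)):
            rss = float(np.sum(res.fun ** 2))
            if best is None or rss < best[0]:
                best = (rss, res.x)
        if best is not None and bb == b0:
            break  # the linearization start converged; no fallback needed

    # boundary of the family closure: constant survival (c -> 1), whose
    # least-squares level is the clipped mean of the data
    kappa = min(max(float(np.mean(s)), 1e-12), 1.0)
    rss_flat = float(np.sum((s - kappa) ** 2))

    if best is None:
        return GompertzFit(math.nan, math.nan, rss_flat, len(g),
                           FitStatus.DEGENERATE)
    rss, x = best
    if rss_flat < rss:  # interior search lost to the boundary optimum
        return GompertzFit(math.nan, math.nan, rss_flat, len(g),
                           FitStatus.DEGENERATE)
    b = float(math.exp(x[0]))
    c = float(1.0 + math.exp(x[1]))
    # optimum pushed onto a bound: no usable mortality acceleration
    status = FitStatus.DEGENERATE if (c - 1.0 < 1e-10 or b < 1e-14) else FitStatus.OK
    fit = GompertzFit(b, c, rss, len(g), status)
    if status is FitStatus.OK:
        fit.median_G = median_lifespan(fit)
        fit.left_censored = b >= math.log(2.0 * fit.a)
    return fit


def median_lifespan(fit: GompertzFit) -> float:
    """Generations at which fitted survival crosses 50%.

    Closed form ``ln(ln 2 / b) / ln c``, valid when S(0) > 0.5 (i.e.
    b < a*ln 2). When survival already starts at or below 50% the median is
    reported as 0 (left-censored).
    """
    if fit.status is not FitStatus.OK:
        raise ValueError(f"cannot take median of a {fit.status.value} fit")
    if fit.b >= math.log(2.0 * fit.a):
        return 0.0
    return math.log(math.log(2.0 * fit.a) / fit.b) / math.log(fit.c)


# ---------------------------------------------------------------------------
# hypothesis testing and classification
# ---------------------------------------------------------------------------

def f_test_vs_wildtype(
    mutant_points: Tuple[np.ndarray, np.ndarray],
    wildtype_points: Tuple[np.ndarray, np.ndarray],
    include_origin: bool = False,
) -> Tuple[float, float]:
    """Extra-sum-of-squares F-test for equal survival trends.

    Compares the pooled fit (one shared (b, c) for the concatenated points)
    against separate fits::

        F = ((RSS_pooled - RSS_sep) / 2) / (RSS_sep / (n_total - 4))

    with p from F(2, n_total - 4). Raises ``ValueError`` when either separate
    fit fails or n_total <= 4 (test undefined).
    """
    gm, sm = (np.asarray(a, float) for a in mutant_points)
    gw, sw = (np.asarray(a, float) for a in wildtype_points)
    fit_m = fit_gompertz(gm, sm, include_origin=include_origin)
    fit_w = fit_gompertz(gw, sw, include_origin=include_origin)
    # a boundary (degenerate) optimum still yields a valid least-squares RSS;
    # only non-convergence invalidates the test
    if fit_m.status is FitStatus.FAILED or fit_w.status is FitStatus.FAILED:
        raise ValueError("both point sets must fit successfully")
    n_total = fit_m.n_points + fit_w.n_points
    if n_total <= 4:
        raise ValueError("test undefined with n_total <= 4")
    gp = np.concatenate([gm, gw])
    sp = np.concatenate([sm, sw])
    fit_p = fit_gompertz(gp, sp, include_origin=False)
    if fit_p.status is FitStatus.FAILED:
        raise ValueError("pooled fit did not converge")
    rss_sep = fit_m.rss + fit_w.rss
    rss_pool = fit_p.rss
    if rss_sep <= 1e-16 * n_total:  # noise-free identical curves
        return 0.0, 1.0
    f_stat = max(0.0, ((rss_pool - rss_sep) / 2.0) / (rss_sep / (n_total - 4)))
    p = float(stats.f.sf(f_stat, 2, n_total - 4))
    return float(f_stat), p


class Classification(str, enum.Enum):
    LONG = "long"
    SHORT = "short"
    NORMAL = "normal"
    UNCLASSIFIED = "unclassified"


def classify_strains(scores: Mapping[str, float]) -> dict[str, Classification]:
    """Mean +/- 1 sample-SD rule over valid lifespan scores.

    Long if score > mean + SD, short if score < mean - SD; strains without a
    valid (finite) score are unclassified, and with fewer than 3 valid scores
    everything is unclassified.
    """
    vals = {k: v for k, v in scores.items() if v is not None and np.isfinite(v)}
    out = {k: Classification.UNCLASSIFIED for k in scores}
    if len(vals) < 3:
        return out
    arr = np.array(list(vals.values()))
    mean, sd = arr.mean(), arr.std(ddof=1)
    for k, v in vals.items():
        if v > mean + sd:
            out[k] = Classification.LONG
        elif v < mean - sd:
            out[k] = Classification.SHORT
        else:
            out[k] = Classification.NORMAL
    return out


# ---------------------------------------------------------------------------
# screen orchestration
# ---------------------------------------------------------------------------

def run_screen(
    replicates: Mapping[str, ScreenReplicate],
    wildtype_ids: Sequence[str],
    config: Optional[ScreenConfig] = None,
) -> pd.DataFrame:
    """End-to-end screen analysis across biological replicates.

    Per replicate and strain: fractions -> survival -> generations -> Gompertz
    fit -> median lifespan. The reported ``rls_score`` is the unweighted mean
    of per-replicate medians. Each strain's survival points pooled across
    replicates are tested against the wild-type reference (all wild-type
    strains, all replicates) with the extra-sum-of-squares F-test;
    Benjamini-Hochberg q-values are reported across strains. Classification
    uses the +/- 1 SD rule on ``rls_score``. Deterministic given inputs.

    Returns a DataFrame indexed by strain_id with columns rls_score,
    median_<rep>..., b, c, rss, F_stat, p_value, q_value, classification,
    flags.
    """
    config = config or ScreenConfig()
    if not replicates:
        raise ValueError("no replicates supplied")
    if not wildtype_ids:
        raise ValueError("at least one wild-type reference strain is required")

    rep_ids = list(replicates)
    strains = list(replicates[rep_ids[0]].counts_up.strains)
    missing_wt = [w for w in wildtype_ids if w not in strains]
    if missing_wt:
        raise ValueError(f"wild-type reference strains absent from counts: {missing_wt}")

    flags: dict[str, set] = {s: set() for s in strains}

    # USC-count exclusion: total tag counts in the unsorted sample
    excluded: set = set()
    for rep in replicates.values():
        usc = rep.meta.sample_for("unsorted", 0)
        up = rep.counts_up.to_frame()[usc]
        dn = rep.counts_dn.to_frame()[usc]
        low = (up + dn) < config.min_usc_count
        for s in up.index[low]:
            excluded.add(s)
            flags[s].add("low_usc")

    # per-replicate trajectories and fits
    medians: dict[str, dict[str, float]] = {s: {} for s in strains}
    points_all: dict[str, list] = {s: [] for s in strains}
    for rid in rep_ids:
        rep = replicates[rid]
        fo, fy = compute_fractions(rep.counts_up, rep.counts_dn, rep.meta,
                                   config.pseudocount, config.tag_policy)
        for s in strains:
            traj = StrainTrajectory.from_fractions(
                s, fo.loc[s].to_numpy(), fy.loc[s].to_numpy(), rep.meta)
            if np.any(np.isnan(traj.S[1:])) or np.any(np.isnan(traj.Gcum[1:])):
                flags[s].add("zero_fraction")
            if np.nanmax(traj.S) > 1.0:
                flags[s].add("survival_gt_1")
            g, sv = traj.fit_points(config.rounds_used)
            points_all[s].append((g, sv))
            if s in excluded:
                continue
            try:
                fit = fit_gompertz(g, sv, include_origin=False)
            except ValueError:
                flags[s].add("fit_failed")
                continue
            if fit.status is FitStatus.OK:
                medians[s][rid] = fit.median_G
                if fit.left_censored:
                    flags[s].add("left_censored")
            else:
                flags[s].add(f"fit_{fit.status.value}")

    # pooled (across replicates) per-strain points; wild-type reference
    def _concat(point_sets):
        gs = np.concatenate([g for g, _ in point_sets])
        ss = np.concatenate([sv for _, sv in point_sets])
        return gs, ss

    wt_points = _concat([p for w in wildtype_ids for p in points_all[w]])
    try:
        wt_fit = fit_gompertz(*wt_points, include_origin=False)
        wt_ok = wt_fit.status is FitStatus.OK
    except ValueError:
        wt_ok = False

    rows = []
    scores: dict[str, float] = {}
    for s in strains:
        reps = medians[s]
        # a strain must have a valid fit in every replicate to be scored
        score = float(np.mean([reps[r] for r in rep_ids])) if len(reps) == len(rep_ids) else math.nan
        scores[s] = score
        b = c = rss = f_stat = p = math.nan
        if s not in excluded:
            try:
                fit = fit_gompertz(*_concat(points_all[s]), include_origin=False)
                if fit.status is FitStatus.OK:
                    b, c, rss = fit.b, fit.c, fit.rss
                    if wt_ok:
                        f_stat, p = f_test_vs_wildtype(_concat(points_all[s]), wt_points)
            except ValueError:
                flags[s].add("fit_failed")
        row = {"strain_id": s, "rls_score": score, "b": b, "c": c, "rss": rss,
               "F_stat": f_stat, "p_value": p}
        for rid in rep_ids:
            row[f"median_{rid}"] = reps.get(rid, math.nan)
        rows.append(row)

    out = pd.DataFrame(rows).set_index("strain_id")
    cls = classify_strains(scores)
    out["classification"] = [cls[s].value for s in out.index]

    pv = out["p_value"].to_numpy()
    qv = np.full_like(pv, math.nan)
    ok = np.isfinite(pv)
    if ok.any():
        qv[ok] = stats.false_discovery_control(pv[ok], method="bh")
    out["q_value"] = qv
    out["flags"] = [";".join(sorted(flags[s])) for s in out.index]
    order = (["rls_score"] + [f"median_{r}" for r in rep_ids]
             + ["b", "c", "rss", "F_stat", "p_value", "q_value",
                "classification", "flags"])
    return out[order]


def estimate_recovery_rate(
    replicates: Mapping[str, ScreenReplicate],
    wildtype_ids: Sequence[str],
    expected_wt_median: float,
    config: Optional[ScreenConfig] = None,
    bounds: Tuple[float, float] = (0.05, 1.0),
) -> float:
    """Calibrate a single pooled bead-recovery rate r.

    This is calibration, not inference: it searches for the r (applied to
    every round of every replicate) that makes the wild-type reference
    strains' mean fitted median lifespan equal ``expected_wt_median``, which
    the user supplies from an external source such as a manual assay.
    """
    config = config or ScreenConfig()

    def wt_mean_median(r: float) -> float:
        reps = {}
        for rid, rep in replicates.items():
            meta = SortMetadata(rep.meta.To.copy(), rep.meta.Ty.copy(),
                                np.full(rep.meta.rounds, r), dict(rep.meta.roles))
            reps[rid] = ScreenReplicate(rep.counts_up, rep.counts_dn, meta)
        res = run_screen(reps, wildtype_ids, config)
        return float(np.nanmean(res.loc[list(wildtype_ids), "rls_score"]))

    def objective(r: float) -> float:
        m = wt_mean_median(r)
        return (m - expected_wt_median) ** 2 if np.isfinite(m) else 1e12

    res = optimize.minimize_scalar(objective, bounds=bounds, method="bounded",
                                   options={"xatol": 1e-4})
    return float(res.x)
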