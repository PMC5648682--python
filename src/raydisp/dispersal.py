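"""Natal/breeding dispersal events and the statistics that test them.

Dispersal events are derived from longitudinal capture records: a natal
event links the natal nest box to the first recorded breeding box; breeding
events link successive breeding records of the same adult.  The module
provides the Kolmogorov-Smirnov sex comparison, a distance-decay regression
of recapture probability, two Monte Carlo randomization null models for
median dispersal distances (uniform assignment and exponential "random
walk" assignment), hierarchical log-linear analysis of the dispersal-status
frequency table, and simple contingency-table summaries.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from raydisp.territory import DISPERSED, TerritoryModel, classify_dispersal, to_territory_units

__all__ = [
    "DispersalEvent",
    "KSResult",
    "DecayFit",
    "NullModelResult",
    "LogLinearResult",
    "extract_dispersal_events",
    "ks_two_sample",
    "fit_distance_decay",
    "available_boxes_by_year",
    "monte_carlo_median_test",
    "loglinear_backward",
    "contingency_summaries",
]

NATAL = "natal"
BREEDING = "breeding"


@dataclass
class DispersalEvent:
    individual_id: str
    sex: str
    type: str  # 'natal' | 'breeding'
    origin_box: str
    destination_box: str
    year_from: int
    year_to: int
    distance_m: float
    territory_units: float | None
    status: str | None  # 'dispersed' | 'nondispersed'


@dataclass
class KSResult:
    D: float
    Z: float
    p_value: float
    n1: int
    n2: int


@dataclass
class DecayFit:
    """log-linear fit of per-box recapture probability against distance."""

    decay_rate: float | None  # lambda, per metre; None if fallback
    intercept: float | None
    bin_centres_m: np.ndarray
    probabilities: np.ndarray
    uniform_fallback: bool


@dataclass
class NullModelResult:
    model: str  # 'uniform' | 'random_walk'
    observed_median_m: float
    null_medians_m: np.ndarray
    p_lower: float
    p_upper: float
    n_sim: int
    seed: int


@dataclass
class LogLinearResult:
    retained_terms: list
    removed_terms: list  # (term, G2, df, p) in removal order
    final_G2: float
    final_df: int
    final_p: float
    warnings: list = field(default_factory=list)


# --------------------------------------------------------------------------
# event extraction
# --------------------------------------------------------------------------

def extract_dispersal_events(
    captures: pd.DataFrame,
    boxes: pd.DataFrame,
    models_by_year: dict[int, TerritoryModel] | None = None,
    event_set: str = "expanded",
) -> pd.DataFrame:
    """Derive natal and breeding dispersal events from capture records.

    One natal event per recruit (nestling record followed by a first adult
    record) and one breeding event per pair of successive adult records of
    the same individual.  ``event_set='reduced'`` keeps only the first
    breeding event per individual.  If territory models are given, distances
    are converted to territory units and classified dispersed/nondispersed
    with the threshold of the recapture year.
    """
    if event_set not in ("expanded", "reduced"):
        raise ValueError(f"unknown event_set {event_set!r}")
    known = set(boxes["box_id"])
    bad = set(captures["box_id"]) - known
    if bad:
        raise ValueError(f"captures reference unknown boxes: {sorted(bad)}")
    coords = boxes.set_index("box_id")[["x_m", "y_m"]]

    events: list[DispersalEvent] = []
    for ind, grp in captures.groupby("individual_id", sort=True):
        grp = grp.sort_values("year", kind="stable")
        if grp.duplicated(subset=["year", "stage"]).any():
            raise ValueError(f"duplicate same-year records for {ind!r}")
        sex = str(grp["sex"].iloc[0])
        nest = grp[grp["stage"] == "nestling"]
        adult = grp[grp["stage"] == "adult"]
        if len(nest) and len(adult):
            first = adult.iloc[0]
            events.append(_make_event(
                ind, sex, NATAL,
                str(nest.iloc[0]["box_id"]), str(first["box_id"]),
                int(nest.iloc[0]["year"]), int(first["year"]),
                coords, models_by_year,
            ))
        if len(adult) >= 2:
            rows = list(adult.itertuples(index=False))
            pairs = zip(rows[:-1], rows[1:])
            if event_set == "reduced":
                pairs = itertools.islice(pairs, 1)
            for a, b in pairs:
                events.append(_make_event(
                    ind, sex, BREEDING,
                    str(a.box_id), str(b.box_id), int(a.year), int(b.year),
                    coords, models_by_year,
                ))
    return pd.DataFrame([vars(e) for e in events])


def _make_event(ind, sex, etype, origin, dest, y0, y1, coords, models):
    dx = coords.loc[dest] - coords.loc[origin]
    dist = float(np.hypot(dx["x_m"], dx["y_m"]))
    tu = status = None
    if models and y1 in models:
        m = models[y1]
        tu = to_territory_units(dist, m.mean_diameter_m)
        status = classify_dispersal(dist, m.ci95_upper_m)
    return DispersalEvent(ind, sex, etype, origin, dest, y0, y1, dist, tu, status)


# --------------------------------------------------------------------------
# Kolmogorov-Smirnov sex comparison
# --------------------------------------------------------------------------

def ks_two_sample(distances_f, distances_m) -> KSResult:
    """Two-sided two-sample KS test with the normalized statistic Z.

    Z = D * sqrt(n*m/(n+m)); the p-value follows scipy's sample-size rule
    (exact for small samples, asymptotic otherwise).
    """
    a = np.asarray(distances_f, dtype=float)
    b = np.asarray(distances_m, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="auto")
    z = float(res.statistic * np.sqrt(a.size * b.size / (a.size + b.size)))
    return KSResult(float(res.statistic), z, float(res.pvalue), a.size, b.size)


# --------------------------------------------------------------------------
# distance-decay regression (exponential null model input)
# --------------------------------------------------------------------------

def fit_distance_decay(
    captures: pd.DataFrame,
    boxes: pd.DataFrame,
    bin_width_m: float = 100.0,
) -> DecayFit:
    """Regress per-box recapture probability on distance from the natal box.

    For every recruit, all box-to-natal-box distances enter the candidate
    counts and the settled box enters the recapture counts.  Binned
    probabilities are fitted as log(p) = a - lambda*d by least squares over
    bins with p > 0; a non-positive fitted lambda triggers a uniform-model
    fallback (flagged, with a warning).
    """
    events = extract_dispersal_events(captures, boxes)
    natal = events[events["type"] == NATAL] if len(events) else events
    if len(natal) == 0:
        raise ValueError("no natal recaptures; cannot fit distance decay")
    xy = boxes[["x_m", "y_m"]].to_numpy(float)
    box_xy = {b: xy[i] for i, b in enumerate(boxes["box_id"])}

    max_d = 0.0
    for o in natal["origin_box"]:
        d = np.hypot(*(xy - box_xy[o]).T)
        max_d = max(max_d, float(d.max()))
    edges = np.arange(0.0, max_d + bin_width_m, bin_width_m)
    if len(edges) < 4:
        raise ValueError("need >= 3 distance bins; decrease bin_width_m")
    candidates = np.zeros(len(edges) - 1)
    recaptures = np.zeros(len(edges) - 1)
    for _, ev in natal.iterrows():
        d = np.hypot(*(xy - box_xy[ev["origin_box"]]).T)
        candidates += np.histogram(d, bins=edges)[0]
        k = min(int(ev["distance_m"] // bin_width_m), len(recaptures) - 1)
        recaptures[k] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(candidates > 0, recaptures / np.maximum(candidates, 1), np.nan)
    centres = 0.5 * (edges[:-1] + edges[1:])
    ok = np.isfinite(prob) & (prob > 0)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 nonempty distance bins with recaptures")
    # weight bins by recapture counts (inverse variance of log p under
    # Poisson counts); unweighted fits are dominated by sparse far bins,
    # where dropping zero-recapture bins biases the slope towards zero
    w = np.sqrt(recaptures[ok])
    slope, intercept = np.polyfit(centres[ok], np.log(prob[ok]), 1, w=w)
    lam = -float(slope)
    if lam <= 0:
        warnings.warn(
            "fitted distance-decay rate is non-positive; falling back to the "
            "uniform assignment model", stacklevel=2,
        )
        return DecayFit(None, None, centres, prob, True)
    return DecayFit(lam, float(intercept), centres, prob, False)


# --------------------------------------------------------------------------
# Monte Carlo null models for median dispersal distance
# --------------------------------------------------------------------------

def available_boxes_by_year(
    events: pd.DataFrame, captures: pd.DataFrame, boxes: pd.DataFrame
) -> dict[int, list[str]]:
    """Boxes available for random assignment in each recapture year.

    Available = boxes not occupied by a breeding pair that year, plus the
    destination boxes of the focal events themselves (occupied by the very
    birds being randomized).
    """
    adults = captures[captures["stage"] == "adult"]
    occupied = adults.groupby("year")["box_id"].agg(set).to_dict()
    out: dict[int, list[str]] = {}
    for year, grp in events.groupby("year_to"):
        occ = set(occupied.get(year, set()))
        focal = set(grp["destination_box"])
        avail = sorted((set(boxes["box_id"]) - occ) | focal)
        out[int(year)] = avail
    return out


def monte_carlo_median_test(
    events: pd.DataFrame,
    available: dict[int, list[str]],
    boxes: pd.DataFrame,
    model: str = "uniform",
    decay_rate: float | None = None,
    n_sim: int = 1000,
    seed: int = 0,
) -> NullModelResult:
    """Randomization test of the observed median dispersal distance.

    Each simulation reassigns every focal bird to one of the boxes available
    in its recapture year, without replacement within a year.  The uniform
    model assigns with equal probability; the random-walk model weights box
    b at distance d from the bird's origin by exp(-decay_rate*d).  One-tailed
    exact probabilities use the +1 correction:
    p_lower = (1 + #{null median <= observed}) / (n_sim + 1).
    """
    if model not in ("uniform", "random_walk"):
        raise ValueError(f"unknown null model {model!r}")
    if model == "random_walk" and decay_rate is None:
        raise ValueError("random_walk model requires decay_rate")
    if len(events) == 0:
        raise ValueError("no events to test")
    xy = {b: np.array([x, y]) for b, x, y in
          zip(boxes["box_id"], boxes["x_m"], boxes["y_m"])}
    rng = np.random.default_rng(seed)

    groups = []
    for year, grp in events.groupby("year_to"):
        pool = available.get(int(year))
        if pool is None or len(pool) < len(grp):
            raise ValueError(
                f"year {year}: {len(grp)} birds but only "
                f"{0 if pool is None else len(pool)} available boxes"
            )
        origins = np.stack([xy[o] for o in grp["origin_box"]])
        pool_xy = np.stack([xy[b] for b in pool])
        # distances from each bird's origin to each available box
        dmat = np.linalg.norm(origins[:, None, :] - pool_xy[None, :, :], axis=2)
        groups.append(dmat)

    observed = float(np.median(events["distance_m"].to_numpy(float)))
    null_medians = np.empty(n_sim)
    for s in range(n_sim):
        dists: list[float] = []
        for dmat in groups:
            k, nb = dmat.shape
            if model == "uniform":
                picks = rng.choice(nb, size=k, replace=False)
                dists.extend(dmat[np.arange(k), picks])
            else:
                taken = np.zeros(nb, dtype=bool)
                for i in rng.permutation(k):
                    w = np.exp(-decay_rate * dmat[i])
                    w[taken] = 0.0
                    w_sum = w.sum()
                    if w_sum <= 0:  # numerically dead tail: uniform on the rest
                        w = (~taken).astype(float)
                        w_sum = w.sum()
                    j = rng.choice(nb, p=w / w_sum)
                    taken[j] = True
                    dists.append(dmat[i, j])
        null_medians[s] = np.median(dists)

    p_lower = (1 + int((null_medians <= observed).sum())) / (n_sim + 1)
    p_upper = (1 + int((null_medians >= observed).sum())) / (n_sim + 1)
    return NullModelResult(model, observed, null_medians, p_lower, p_upper,
                           n_sim, seed)


# --------------------------------------------------------------------------
# hierarchical log-linear analysis of the status x sex x population table
# --------------------------------------------------------------------------

_FACTORS = ("status", "sex", "population")


def loglinear_backward(table: np.ndarray, alpha: float = 0.05) -> LogLinearResult:
    """Backward elimination over hierarchical log-linear models of a 2x2x2 table.

    ``table[status, sex, population]`` holds counts.  Starting from the
    saturated model, the three-way term and then the weakest two-way terms
    are removed while the likelihood-ratio (G^2) test for their deletion is
    nonsignificant at ``alpha``.  Main effects are always retained.  A zero
    margin triggers a 0.5 continuity correction on all cells (flagged).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2, 2):
        raise ValueError(f"expected a 2x2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    warns: list[str] = []
    for ax in range(3):
        if (t.sum(axis=tuple(i for i in range(3) if i != ax)) == 0).any():
            t = t + 0.5
            warns.append("zero margin: added 0.5 continuity correction to all cells")
            warnings.warn(warns[-1], stacklevel=2)
            break

    import statsmodels.api as sm

    levels = [(i, j, k) for i in range(2) for j in range(2) for k in range(2)]
    y = np.array([t[ijk] for ijk in levels])
    cols = {
        "status": np.array([i for i, _, _ in levels], float),
        "sex": np.array([j for _, j, _ in levels], float),
        "population": np.array([k for _, _, k in levels], float),
    }

    def design(terms):
        X = [np.ones(8)]
        for f in _FACTORS:
            X.append(cols[f])
        for term in terms:
            parts = term.split(":")
            v = np.ones(8)
            for p in parts:
                v = v * cols[p]
            X.append(v)
        return np.column_stack(X)

    def deviance(terms):
        X = design(terms)
        with warnings.catch_warnings():
            # the saturated model triggers a perfect-separation note; its
            # fitted means (the counts themselves) are exactly what we need
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        return float(fit.deviance)

    two_way = ["status:sex", "status:population", "sex:population"]
    three_way = "status:sex:population"
    current = two_way + [three_way]
    removed: list[tuple[str, float, int, float]] = []

    # step 1: the three-way interaction
    g2 = deviance(two_way) - deviance(current)
    p = float(stats.chi2.sf(g2, 1))
    if p > alpha:
        current = list(two_way)
        removed.append((three_way, g2, 1, p))

    # step 2: weakest two-way terms, one at a time
    if three_way not in current:
        while True:
            candidates = []
            for term in [x for x in current]:
                rest = [x for x in current if x != term]
                g2 = deviance(rest) - deviance(current)
                candidates.append((term, g2, float(stats.chi2.sf(g2, 1))))
            candidates.sort(key=lambda c: c[2], reverse=True)
            if not candidates or candidates[0][2] <= alpha:
                break
            term, g2, p = candidates[0]
            current.remove(term)
            removed.append((term, g2, 1, p))

    final_g2 = deviance(current)
    final_df = 8 - design(current).shape[1]
    final_p = float(stats.chi2.sf(final_g2, final_df)) if final_df > 0 else 1.0
    retained = list(_FACTORS) + current
    return LogLinearResult(retained, removed, final_g2, final_df, final_p, warns)


# --------------------------------------------------------------------------
# contingency summaries (frequency of breeding dispersal)
# --------------------------------------------------------------------------

def contingency_summaries(table: pd.DataFrame) -> dict:
    """Percent dispersed per site and nest-site fidelity per sex.

    ``table`` has one row per (site, status) with integer columns
    'females'/'males', status in {'nondispersed', 'dispersed'}.  Percentages
    are rounded to the nearest integer.
    """
    t = table.copy()
    if (t[["females", "males"]].to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    t["total"] = t["females"] + t["males"]
    out: dict[str, float] = {}
    for site, grp in t.groupby("site", sort=False):
        disp = grp.loc[grp["status"] == "dispersed", "total"].sum()
        tot = grp["total"].sum()
        out[f"dispersed_pct_{site}"] = round(100.0 * disp / tot) if tot else 0
    for sex in ("females", "males"):
        stay = t.loc[t["status"] == "nondispersed", sex].sum()
        tot = t[sex].sum()
        out[f"fidelity_pct_{sex}"] = round(100.0 * stay / tot) if tot else 0
    return out
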