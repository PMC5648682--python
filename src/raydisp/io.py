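"""Table readers/writers, run configuration and the pipeline orchestration.

Three plain-text formats are supported:

* coordinates CSV: box_id, x_m, y_m, site (planar metres, UTM-style);
* captures CSV: individual_id, sex (F/M), stage (nestling/adult), year,
  box_id;
* genotypes in a GenAlEx-dialect CSV: two integer allele columns per locus,
  0 for a missing allele, preceded by three header rows (counts, title,
  locus names).

Readers validate rather than coerce; writers round-trip through the readers.
``run_pipeline`` executes territory -> dispersal -> demography -> genetics
on one configured site, drawing an independent logged sub-seed for every
stochastic stage.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from raydisp import demography, dispersal, genetics, territory

__all__ = [
    "AnalysisConfig",
    "RunReport",
    "read_boxes",
    "write_boxes",
    "read_captures",
    "write_captures",
    "read_genotype_table",
    "write_genotype_table",
    "breeding_adult_coordinates",
    "run_pipeline",
]

SEXES = {"F", "M"}
STAGES = {"nestling", "adult"}


# --------------------------------------------------------------------------
# coordinates and captures
# --------------------------------------------------------------------------

def read_boxes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"box_id": str, "site": str})
    _require_columns(df, ["box_id", "x_m", "y_m", "site"], path)
    if df["box_id"].duplicated().any():
        dup = df.loc[df["box_id"].duplicated(), "box_id"].tolist()
        raise ValueError(f"{path}: duplicated box ids {dup}")
    df["x_m"] = pd.to_numeric(df["x_m"], errors="raise")
    df["y_m"] = pd.to_numeric(df["y_m"], errors="raise")
    return df


def write_boxes(boxes: pd.DataFrame, path) -> None:
    boxes[["box_id", "x_m", "y_m", "site"]].to_csv(path, index=False)


def read_captures(path, boxes: pd.DataFrame | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["individual_id", "sex", "stage", "year", "box_id"], path)
    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        raise ValueError(
            f"{path}: invalid sex at line(s) {_lines(df, bad_sex)}; expected F or M"
        )
    bad_stage = ~df["stage"].isin(STAGES)
    if bad_stage.any():
        raise ValueError(
            f"{path}: invalid stage at line(s) {_lines(df, bad_stage)}"
        )
    years = pd.to_numeric(df["year"], errors="coerce")
    bad_year = years.isna() | (years != years.round())
    if bad_year.any():
        raise ValueError(
            f"{path}: malformed year at line(s) {_lines(df, bad_year)}"
        )
    df["year"] = years.astype(int)
    if boxes is not None:
        unknown = sorted(set(df["box_id"]) - set(boxes["box_id"]))
        if unknown:
            raise ValueError(f"{path}: unknown box ids {unknown}")
    return df


def write_captures(captures: pd.DataFrame, path) -> None:
    captures[["individual_id", "sex", "stage", "year", "box_id"]].to_csv(
        path, index=False
    )


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def _lines(df: pd.DataFrame, mask) -> list:
    # +2: one for the header row, one for 1-based numbering
    return [int(i) + 2 for i in df.index[mask]][:10]


# --------------------------------------------------------------------------
# GenAlEx-dialect genotypes
# --------------------------------------------------------------------------

def write_genotype_table(
    genotypes: pd.DataFrame, path, title: str = "raydisp genotypes"
) -> None:
    """Write a two-column-per-locus genotype table (0 = missing allele)."""
    allele_cols = [c for c in genotypes.columns if c != "individual_id"]
    loci = [allele_cols[i][:-2] for i in range(0, len(allele_cols), 2)]
    n = len(genotypes)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([len(loci), n, 1, n])
        w.writerow([title])
        header = ["Ind", "Pop"]
        for L in loci:
            header.extend([L, ""])
        w.writerow(header)
        for row in genotypes.itertuples(index=False):
            vals = [getattr(row, c) for c in allele_cols]
            w.writerow([row.individual_id, "1", *[int(v) for v in vals]])


def read_genotype_table(path) -> pd.DataFrame:
    """Read a GenAlEx-dialect genotype CSV into a two-column-per-locus table."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise ValueError(f"{path}: not a genotype table (needs 3 header rows)")
    try:
        n_loci = int(rows[0][0])
        n_samples = int(rows[0][1])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: malformed count header") from exc
    header = rows[2]
    loci = [h for h in header[2:] if h]
    if len(loci) != n_loci:
        raise ValueError(
            f"{path}: header names {len(loci)} loci but count row says {n_loci}"
        )
    data = [r for r in rows[3:] if any(field.strip() for field in r)]
    if len(data) != n_samples:
        raise ValueError(
            f"{path}: {len(data)} data rows but count row says {n_samples}"
        )
    ids, alleles = [], []
    for r in data:
        vals = [v for v in r[2:] if v != ""]
        if len(vals) != 2 * n_loci:
            k = len(vals) // 2
            locus = loci[min(k, n_loci - 1)]
            raise ValueError(
                f"{path}: individual {r[0]!r} has an odd or short allele "
                f"column count near locus {locus!r}"
            )
        ids.append(r[0])
        alleles.append([int(v) for v in vals])
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicated individual ids {dup}")
    out = {"individual_id": ids}
    arr = np.asarray(alleles, dtype=int)
    for k, L in enumerate(loci):
        out[f"{L}_1"] = arr[:, 2 * k]
        out[f"{L}_2"] = arr[:, 2 * k + 1]
    return pd.DataFrame(out)


def breeding_adult_coordinates(
    captures: pd.DataFrame, boxes: pd.DataFrame, years=None
) -> pd.DataFrame:
    """Per-individual breeding coordinates: box of the first adult record.

    Optionally restricted to a window of years (e.g. the genotyped seasons).
    Returns individual_id, sex, x_m, y_m.
    """
    adults = captures[captures["stage"] == "adult"]
    if years is not None:
        adults = adults[adults["year"].isin(list(years))]
    first = (adults.sort_values("year", kind="stable")
             .groupby("individual_id", sort=True).first().reset_index())
    coords = boxes.set_index("box_id")[["x_m", "y_m"]]
    first = first.join(coords, on="box_id")
    return first[["individual_id", "sex", "x_m", "y_m"]]


# --------------------------------------------------------------------------
# configuration and run report
# --------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    site: str
    captures: str
    boxes: str
    genotypes: str | None = None
    distance_classes: list = field(default_factory=lambda: [150, 300, 450, 600])
    multi_dclass_bounds: list | None = None
    n_boot: int = 1000
    n_perm: int = 1000
    n_sim: int = 1000
    lsa_neighbors: int = 14
    decay_bin_width_m: float = 100.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {unknown}")
        missing = [k for k in ("site", "captures", "boxes") if k not in raw]
        if missing:
            raise ValueError(f"{path}: missing required keys {missing}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class RunReport:
    version: str
    config: dict
    seeds: dict
    results: dict
    warnings: list = field(default_factory=list)
    failures: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "RunReport":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        return cls(**json.loads(text))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: AnalysisConfig) -> RunReport:
    """Run territory -> dispersal -> demography -> genetics on one site.

    Every stochastic stage consumes an independent sub-seed derived from
    ``config.seed``; identical config and seed give identical reports.
    Stage failures are recorded in the report and reflected in the CLI exit
    code rather than raised.
    """
    from raydisp import __version__

    ss = np.random.SeedSequence(config.seed)
    subseeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                for name, s in zip(
                    ["dispersal", "demography", "genetics"], ss.spawn(3))}
    report = RunReport(__version__, dataclasses.asdict(config), subseeds, {})

    boxes = read_boxes(config.boxes)
    captures = read_captures(config.captures, boxes=boxes)
    genotypes = None
    if config.genotypes is not None:
        if not Path(config.genotypes).exists():
            raise FileNotFoundError(
                f"genotype file {config.genotypes!r} does not exist"
            )
        genotypes = read_genotype_table(config.genotypes)

    models = {}
    try:
        models = territory.territory_models_by_year(captures, boxes)
        report.results["territory"] = {
            str(y): {
                "n_pairs": len(m.tiles),
                "mean_diameter_m": m.mean_diameter_m,
                "se_diameter_m": m.se_diameter_m,
                "ci95_upper_m": m.ci95_upper_m,
            }
            for y, m in models.items()
        }
    except Exception as exc:  # noqa: BLE001 - partial report contract
        report.failures.append(f"territory: {exc}")

    events = pd.DataFrame()
    try:
        events = dispersal.extract_dispersal_events(captures, boxes, models)
        report.results["dispersal"] = _dispersal_stage(
            events, captures, boxes, config, subseeds["dispersal"]
        )
    except Exception as exc:  # noqa: BLE001
        report.failures.append(f"dispersal: {exc}")

    try:
        report.results["demography"] = _demography_stage(
            captures, subseeds["demography"]
        )
    except Exception as exc:  # noqa: BLE001
        report.failures.append(f"demography: {exc}")

    if genotypes is not None:
        try:
            report.results["genetics"] = _genetics_stage(
                genotypes, captures, boxes, config, subseeds["genetics"]
            )
        except Exception as exc:  # noqa: BLE001
            report.failures.append(f"genetics: {exc}")
    return report


def _dispersal_stage(events, captures, boxes, config, seed):
    out: dict = {"n_events": len(events)}
    if len(events) == 0:
        return out
    for etype in ("natal", "breeding"):
        ev = events[events["type"] == etype]
        sub: dict = {"n": len(ev)}
        f = ev.loc[ev["sex"] == "F", "distance_m"]
        m = ev.loc[ev["sex"] == "M", "distance_m"]
        sub["median_f_m"] = float(f.median()) if len(f) else None
        sub["median_m_m"] = float(m.median()) if len(m) else None
        if len(f) and len(m):
            ks = dispersal.ks_two_sample(f, m)
            sub["ks"] = {"D": ks.D, "Z": ks.Z, "p": ks.p_value}
        if len(ev):
            avail = dispersal.available_boxes_by_year(ev, captures, boxes)
            try:
                mc = dispersal.monte_carlo_median_test(
                    ev, avail, boxes, model="uniform",
                    n_sim=config.n_sim, seed=seed,
                )
                sub["mc_uniform"] = {"observed_median_m": mc.observed_median_m,
                                     "p_lower": mc.p_lower, "p_upper": mc.p_upper}
            except ValueError as exc:
                sub["mc_uniform"] = {"skipped": str(exc)}
            try:
                decay = dispersal.fit_distance_decay(
                    captures, boxes, config.decay_bin_width_m
                )
                if not decay.uniform_fallback:
                    mc = dispersal.monte_carlo_median_test(
                        ev, avail, boxes, model="random_walk",
                        decay_rate=decay.decay_rate,
                        n_sim=config.n_sim, seed=seed + 1,
                    )
                    sub["mc_random_walk"] = {
                        "decay_rate_per_m": decay.decay_rate,
                        "p_lower": mc.p_lower, "p_upper": mc.p_upper,
                    }
            except ValueError as exc:
                sub["mc_random_walk"] = {"skipped": str(exc)}
        out[etype] = sub
    status = events.dropna(subset=["status"])
    if len(status):
        out["pct_dispersed"] = round(
            100.0 * (status["status"] == "dispersed").mean()
        )
    return out


def _demography_stage(captures, seed):
    H, sexes, years = demography.build_encounter_histories(captures)
    out = {"n_histories": int(H.shape[0]), "years": years, "models": {}}
    for phi_s, p_s in [("constant", "constant"), ("time", "constant"),
                       ("sex", "constant")]:
        try:
            fit = demography.fit_cjs(H, sexes, phi_s, p_s, seed=seed)
            out["models"][f"phi({phi_s})p({p_s})"] = {
                "phi": fit.phi, "p": fit.p, "logLik": fit.log_lik,
                "n_params": fit.n_params, "AICc": fit.aicc, "flags": fit.flags,
            }
        except (ValueError, RuntimeError) as exc:
            out["models"][f"phi({phi_s})p({p_s})"] = {"failed": str(exc)}
    return out


def _genetics_stage(genotypes, captures, boxes, config, seed):
    coords = breeding_adult_coordinates(captures, boxes)
    g = genetics.genotype_matrix_from_tables(genotypes, coords)
    out: dict = {"n_individuals": len(g), "missing_rate": g.missing_rate}
    rng = np.random.default_rng(seed)
    by_sex = {}
    for sex in ("F", "M"):
        sub = g.subset(g.sex == sex)
        if len(sub) < 3:
            by_sex[sex] = {"skipped": "fewer than 3 individuals"}
            continue
        D = genetics.squared_genetic_distance(sub)
        geo = genetics.geographic_distances(sub.coords)
        res = genetics.correlogram(
            D, geo, config.distance_classes,
            n_boot=config.n_boot, n_perm=config.n_perm,
            seed=int(rng.integers(2 ** 31)),
        )
        mantel = genetics.mantel_test(
            np.nan_to_num(D.values), geo, n_perm=config.n_perm,
            seed=int(rng.integers(2 ** 31)),
        )
        lsa_sig = None
        if len(sub) > config.lsa_neighbors:
            lsa = genetics.local_autocorr_2d(
                sub, config.lsa_neighbors, config.n_perm,
                seed=int(rng.integers(2 ** 31)),
            )
            lsa_sig = float(((lsa["p_value"] <= 0.05) & (lsa["lr"] > 0)).mean())
        by_sex[sex] = {
            "correlogram": [
                {"class": c.label, "n_pairs": c.n_pairs, "r": c.r,
                 "ci": [c.ci_lower, c.ci_upper],
                 "envelope": [c.perm_lower, c.perm_upper],
                 "significant": c.significant}
                for c in res
            ],
            "mantel": {"r_xy": mantel.r_xy, "p": mantel.p_value},
            "lsa_significant_positive_fraction": lsa_sig,
        }
    out["by_sex"] = by_sex
    gm = g.subset(g.sex == "M")
    gf = g.subset(g.sex == "F")
    if len(gm) >= 3 and len(gf) >= 3:
        het = genetics.heterogeneity_tests(
            gf, gm, config.distance_classes, n_perm=config.n_perm,
            seed=int(rng.integers(2 ** 31)),
        )
        out["heterogeneity"] = {
            "classes": het.classes,
            "t2": het.t2, "t2_p": het.t2_p,
            "omega": het.omega, "omega_p": het.omega_p,
        }
    return out
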