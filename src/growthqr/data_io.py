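"""Domain types, delimited-text readers/writers and run configuration.

All on-disk formats are plain delimited text (comma by default, tab
accepted).  Genotypes are coded 2 (AA), 1 (Aa), 0 (aa); marker positions
are in centimorgans.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """Malformed input file: missing columns, bad cells, broken invariants."""


class MissingGenotypeError(FormatError):
    """A genotype call is missing and the policy forbids imputation."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GrowthRecords:
    """Longitudinal weight-age observations for one animal.

    Ages are days (strictly increasing, no duplicates), weights are kg
    (strictly positive).  Three-parameter curve fitting additionally
    requires at least 4 observations; that is enforced at fit time, not
    here, so partially observed animals can still be represented.
    """

    animal_id: str
    ages: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if ages.shape != weights.shape or ages.ndim != 1:
            raise FormatError(f"{self.animal_id}: ages and weights must be 1-D and equal length")
        if ages.size == 0:
            raise FormatError(f"{self.animal_id}: no observations")
        if np.any(ages < 0):
            raise FormatError(f"{self.animal_id}: negative age")
        if np.any(np.diff(ages) <= 0):
            raise FormatError(f"{self.animal_id}: ages must be strictly increasing (duplicate or unsorted age)")
        if np.any(weights <= 0) or not np.all(np.isfinite(weights)):
            raise FormatError(f"{self.animal_id}: weights must be finite and strictly positive")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "weights", weights)

    @property
    def n_obs(self) -> int:
        return int(self.ages.size)

    @property
    def observations(self) -> list[tuple[float, float]]:
        return list(zip(self.ages.tolist(), self.weights.tolist()))


@dataclass(frozen=True)
class GenotypePanel:
    """n animals x p markers of {0,1,2} calls plus a genetic map.

    ``marker_map`` is indexed by marker_id with columns ``chromosome`` and
    ``position_cM``; markers are ordered by (chromosome, position) with
    chromosomes in map-file order.
    """

    animal_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]
    calls: np.ndarray
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls)
        n, p = len(self.animal_ids), len(self.marker_ids)
        if calls.shape != (n, p):
            raise FormatError(f"calls shape {calls.shape} != ({n}, {p})")
        if not np.isin(calls, (0, 1, 2)).all():
            raise FormatError("genotype calls must be in {0, 1, 2}")
        if len(set(self.marker_ids)) != p:
            raise FormatError("marker ids must be unique")
        missing = set(self.marker_ids) - set(self.marker_map.index)
        if missing:
            raise FormatError(f"markers absent from map: {sorted(missing)[:5]}")
        object.__setattr__(self, "calls", calls.astype(np.int8))
        object.__setattr__(self, "animal_ids", tuple(self.animal_ids))
        object.__setattr__(self, "marker_ids", tuple(self.marker_ids))
        for chrom, sub in self.marker_map.loc[list(self.marker_ids)].groupby("chromosome", sort=False):
            if np.any(np.diff(sub["position_cM"].to_numpy()) < 0):
                raise FormatError(f"positions decrease within chromosome {chrom}")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def dosage_matrix(self) -> np.ndarray:
        """Calls as float n x p, the X of the genomic regression."""
        return self.calls.astype(float)


@dataclass(frozen=True)
class Covariates:
    """Fixed-effect factors per animal: sex, lot, halothane genotype."""

    table: pd.DataFrame  # index animal_id; columns sex, lot, halothane

    def __post_init__(self) -> None:
        required = {"sex", "lot", "halothane"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"covariate table missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise FormatError("duplicate animal_id in covariates")
        for col in required:
            if self.table[col].isna().any() or (self.table[col].astype(str) == "").any():
                raise FormatError(f"empty level in covariate {col!r}")

    def for_animals(self, animal_ids: Sequence[str]) -> pd.DataFrame:
        missing = set(animal_ids) - set(self.table.index)
        if missing:
            raise FormatError(f"animals without covariates: {sorted(missing)[:5]}")
        return self.table.loc[list(animal_ids)]


def _default_lambda_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 50.0 + 1e-9, 0.5), 6)


@dataclass
class PipelineConfig:
    """Tuning knobs for a full run; defaults mirror the study design."""

    quantiles: tuple[float, ...] = (0.2, 0.5, 0.8)
    lambda_grid: np.ndarray = field(default_factory=_default_lambda_grid)
    bootstrap_reps: int = 200
    top_fraction: float = 0.025
    seed: int = 0
    age_grid: np.ndarray = field(default_factory=lambda: np.arange(0.0, 151.0, 1.0))

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        self.age_grid = np.asarray(self.age_grid, dtype=float)
        if any(not (0.0 < t < 1.0) for t in self.quantiles):
            raise ValueError("quantiles must lie strictly inside (0, 1)")
        if np.any(self.lambda_grid < 0):
            raise ValueError("lambda grid must be non-negative")
        if self.bootstrap_reps < 2:
            raise ValueError("bootstrap_reps must be >= 2")
        if not (0.0 < self.top_fraction <= 1.0):
            raise ValueError("top_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "quantiles" in raw:
            raw["quantiles"] = tuple(float(t) for t in raw["quantiles"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# readers


def _read_table(path: str | Path, dialect: Optional[str] = None) -> pd.DataFrame:
    sep = {None: None, "csv": ",", "tsv": "\t"}.get(dialect, dialect)
    if sep is None:
        # sniffing requires the python engine, which has no float_precision knob;
        # values are re-parsed column-wise below so precision is preserved
        df = pd.read_csv(path, sep=sep, engine="python", dtype=str, skipinitialspace=True)
        return df
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_phenotypes(path: str | Path, dialect: Optional[str] = None) -> list[GrowthRecords]:
    """Read a long-format weight-age table into per-animal records.

    Expects header columns ``animal_id``, ``age_d``, ``weight_kg``.
    Rows are grouped by animal and sorted by age; the total row count is
    conserved.  Duplicate (animal, age) pairs and non-numeric weights are
    errors that name the offending line.
    """
    df = _read_table(path, dialect)
    for col in ("animal_id", "age_d", "weight_kg"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    for col in ("age_d", "weight_kg"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
            raise FormatError(f"{path}: non-numeric {col} at line {line}")
        df[col] = df[col].astype(float)  # astype, not to_numeric: exact parsing
    dup = df.duplicated(subset=["animal_id", "age_d"], keep=False)
    if dup.any():
        a, t = df.loc[df.index[dup][0], ["animal_id", "age_d"]]
        raise FormatError(f"{path}: duplicate observation for animal {a!r} at age {t:g}")
    records = []
    for animal, sub in df.groupby("animal_id", sort=True):
        sub = sub.sort_values("age_d")
        records.append(
            GrowthRecords(str(animal), sub["age_d"].to_numpy(float), sub["weight_kg"].to_numpy(float))
        )
    assert sum(r.n_obs for r in records) == len(df)
    return records


def read_genotypes(
    geno_path: str | Path,
    map_path: str | Path,
    missing_policy: str = "error",
    dialect: Optional[str] = None,
) -> GenotypePanel:
    """Read genotype and map files into a :class:`GenotypePanel`.

    Genotype file: one row per animal, first column ``animal_id``, remaining
    columns one per marker with calls in {0,1,2} or empty/NA.  Map file:
    columns ``marker_id``, ``chr``, ``pos_cM``.  Markers are reordered by
    (chromosome, position); chromosome order follows the map file.

    ``missing_policy``: ``"error"`` rejects any missing call, naming the
    cell; ``"mode_impute"`` replaces each missing call by the marker's most
    frequent observed call, ties resolved toward the smallest call value.
    """
    if missing_policy not in ("error", "mode_impute"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    geno = _read_table(geno_path, dialect)
    if "animal_id" not in geno.columns:
        raise FormatError(f"{geno_path}: missing required column 'animal_id'")
    geno = geno.set_index("animal_id")
    mp = _read_table(map_path, dialect)
    for col in ("marker_id", "chr", "pos_cM"):
        if col not in mp.columns:
            raise FormatError(f"{map_path}: missing required column {col!r}")
    mp = mp.rename(columns={"chr": "chromosome", "pos_cM": "position_cM"}).set_index("marker_id")
    mp["position_cM"] = mp["position_cM"].astype(float)

    unknown = [m for m in geno.columns if m not in mp.index]
    if unknown:
        raise FormatError(f"{geno_path}: markers absent from map: {unknown[:5]}")

    calls = geno.apply(pd.to_numeric, errors="coerce").to_numpy(float)
    missing_mask = np.isnan(calls)
    if missing_mask.any():
        if missing_policy == "error":
            i, j = np.argwhere(missing_mask)[0]
            raise MissingGenotypeError(
                f"{geno_path}: missing call for animal {geno.index[i]!r}, marker {geno.columns[j]!r}"
            )
        for j in range(calls.shape[1]):
            col = calls[:, j]
            obs = col[~np.isnan(col)]
            if obs.size == 0:
                raise FormatError(f"{geno_path}: marker {geno.columns[j]!r} has no observed calls")
            counts = np.bincount(obs.astype(int), minlength=3)
            col[np.isnan(col)] = int(np.argmax(counts))  # argmax ties -> smallest call
    if not np.isin(calls, (0, 1, 2)).all():
        raise FormatError(f"{geno_path}: genotype calls must be 0, 1 or 2")

    # order markers by map (chromosome in file order, then position)
    chrom_rank = {c: i for i, c in enumerate(mp["chromosome"].drop_duplicates())}
    present = mp.loc[[m for m in mp.index if m in set(geno.columns)]].copy()
    present["_rank"] = present["chromosome"].map(chrom_rank)
    order = present.sort_values(["_rank", "position_cM"], kind="stable").index.tolist()
    col_idx = [geno.columns.get_loc(m) for m in order]
    return GenotypePanel(
        animal_ids=tuple(str(a) for a in geno.index),
        marker_ids=tuple(order),
        calls=calls[:, col_idx].astype(np.int8),
        marker_map=mp[["chromosome", "position_cM"]],
    )


def read_covariates(path: str | Path, dialect: Optional[str] = None) -> Covariates:
    df = _read_table(path, dialect)
    for col in ("animal_id", "sex", "lot", "halothane"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df["animal_id"] = df["animal_id"].astype(str)
    return Covariates(df.set_index("animal_id")[["sex", "lot", "halothane"]].astype(str))


# ---------------------------------------------------------------------------
# report writer

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def write_report(fits, ranked, curves, out_dir: str | Path) -> dict[str, Path]:
    """Write effect tables, a fit summary, ranked-marker and curve tables.

    ``fits``: sequence of (trait, tau, RQRFit, BootstrapSummary-or-None,
    marker_map) tuples; ``ranked``: sequence of (trait, tau, RankedMarkers);
    ``curves``: sequence of GenomicCurve.  Returns the paths written.
    Values are written at full double precision so a read-back reproduces
    them bit-exactly.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write to report directory {out}: {exc}") from exc

    effect_rows, summary_rows = [], []
    for trait, tau, fit, boot, marker_map in fits:
        ids = fit.marker_ids if fit.marker_ids is not None else [f"m{k}" for k in range(fit.beta_hat.size)]
        se = boot.se if boot is not None else np.full(len(ids), np.nan)
        pv = boot.p_value if boot is not None else np.full(len(ids), np.nan)
        for k, mid in enumerate(ids):
            row = {"trait": trait, "tau": tau, "marker_id": mid,
                   "effect": fit.beta_hat[k], "se": se[k], "p_value": pv[k]}
            if marker_map is not None and mid in marker_map.index:
                row["chromosome"] = marker_map.loc[mid, "chromosome"]
                row["position_cM"] = marker_map.loc[mid, "position_cM"]
            else:
                row["chromosome"], row["position_cM"] = "", np.nan
            effect_rows.append(row)
        summary_rows.append({
            "trait": trait, "tau": tau, "lambda": fit.lam, "mu_hat": fit.mu_hat,
            "objective": fit.objective, "pseudo_r1": fit.pseudo_r1, "n_nonzero": fit.n_nonzero,
        })

    ranked_rows = []
    for trait, tau, rk in ranked:
        for row in rk.table.to_dict("records"):
            ranked_rows.append({"trait": trait, "tau": tau, **row})

    curve_rows = []
    for cv in curves:
        low = cv.band_low if cv.band_low is not None else np.full_like(cv.mean_curve, np.nan)
        high = cv.band_high if cv.band_high is not None else np.full_like(cv.mean_curve, np.nan)
        for j, age in enumerate(cv.ages):
            curve_rows.append({"tau": cv.tau, "age_d": age, "mean_weight_kg": cv.mean_curve[j],
                               "band_low_kg": low[j], "band_high_kg": high[j]})

    frames = {
        "effects.csv": pd.DataFrame(effect_rows, columns=[
            "trait", "tau", "marker_id", "effect", "se", "p_value", "chromosome", "position_cM"]),
        "summary.csv": pd.DataFrame(summary_rows, columns=[
            "trait", "tau", "lambda", "mu_hat", "objective", "pseudo_r1", "n_nonzero"]),
        "ranked_markers.csv": pd.DataFrame(ranked_rows, columns=[
            "trait", "tau", "marker_id", "effect_abs", "se", "p_value", "chromosome", "position_cM"]),
        "curves.csv": pd.DataFrame(curve_rows, columns=[
            "tau", "age_d", "mean_weight_kg", "band_low_kg", "band_high_kg"]),
    }
    paths = {}
    for name, frame in frames.items():
        path = out / name
        frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
        paths[name] = path
    return paths


def read_report(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read back the tables written by :func:`write_report`."""
    out = Path(out_dir)
    return {name: pd.read_csv(out / name, float_precision="round_trip")
            for name in ("effects.csv", "summary.csv", "ranked_markers.csv", "curves.csv")}
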