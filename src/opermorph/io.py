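"""Readers and writers: TPS outline files, Newick trees, covariate tables.

The TPS dialect understood here is the one produced by outline digitizers:
records introduced by ``LM=<n>`` optionally followed by ``CURVES=<m>`` /
``POINTS=<n>`` blocks holding the traced curve, then ``ID=``, ``IMAGE=`` and
``SCALE=`` lines.  When a record carries both fixed landmarks and a curve,
the curve is taken as the outline.  Readers reject malformed input rather
than coercing it; every writer/reader pair is a lossless round trip.
"""

from __future__ import annotations

import logging
import sys
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phylo import Phylogeny

__all__ = [
    "OutlineSpec",
    "CovariateTable",
    "read_tps",
    "write_tps",
    "read_newick",
    "write_newick",
    "read_covariates",
    "write_covariates",
    "read_config",
    "get_logger",
    "stage_timer",
    "TPSError",
    "CovariateError",
]

#: fixed grouping vocabularies for Lake Tanganyika cichlid feeding ecology
FEEDING_PREFERENCES = (
    "microinvertebrates/algae",
    "zooplankton",
    "benthic invertebrates",
    "piscivore",
    "scales",
    "generalist",
)
FEEDING_MODES = (
    "ram",
    "sandpicking",
    "rockpicking",
    "scales",
    "algaepicking",
    "suction",
    "benthic invertebrate picking",
)

NUMERIC_COVARIATES = ("d13C", "d15N", "grnDa", "grnVa", "mean_rl", "GLTL", "ER")
CATEGORICAL_COVARIATES = {
    "feeding_preference": FEEDING_PREFERENCES,
    "feeding_mode": FEEDING_MODES,
}


class TPSError(ValueError):
    pass


class CovariateError(ValueError):
    pass


@dataclass
class OutlineSpec:
    """One digitized closed outline: ordered (x, y) points tracing the curve.

    The first point is not repeated at the end (closure is implicit).  When a
    ``SCALE=`` record was present the stored coordinates are already in
    physical units (raw pixels times scale).
    """

    points: np.ndarray
    specimen_id: str = ""
    species_code: str = ""
    image: str = ""
    scale: float | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise TPSError("outline points must be an (n, 2) array")
        if len(self.points) < 3:
            raise TPSError("an outline needs at least 3 points")
        if not np.all(np.isfinite(self.points)):
            raise TPSError("non-finite coordinate in outline")
        if self.scale is not None and not self.scale > 0:
            raise TPSError("SCALE must be positive")
        if not self.species_code and "_" in self.specimen_id:
            # convention: specimen ids are "<species_code>_<number>"
            self.species_code = self.specimen_id.rsplit("_", 1)[0]


def _parse_float_pair(line: str, lineno: int):
    parts = line.split()
    if len(parts) != 2:
        raise TPSError(f"line {lineno}: expected 'x y' coordinate pair, got {line!r}")
    try:
        return float(parts[0]), float(parts[1])
    except ValueError:
        raise TPSError(f"line {lineno}: non-numeric coordinate in {line!r}") from None


def read_tps(path) -> list[OutlineSpec]:
    """Parse a TPS file into a list of :class:`OutlineSpec` (record order kept)."""
    lines = Path(path).read_text().splitlines()
    records = []
    current = None  # dict per record

    def flush():
        if current is None:
            return
        pts = current["curve_points"] if current["curve_points"] else current["lm_points"]
        if current["declared_curve_points"] and len(current["curve_points"]) != sum(
            current["declared_curve_points"]
        ):
            raise TPSError(
                f"record {len(records) + 1}: POINTS= declared "
                f"{sum(current['declared_curve_points'])} points, got "
                f"{len(current['curve_points'])}"
            )
        if not current["curve_points"] and len(current["lm_points"]) != current["n_lm"]:
            raise TPSError(
                f"record {len(records) + 1}: LM= declared {current['n_lm']} points, "
                f"got {len(current['lm_points'])}"
            )
        pts = np.asarray(pts, dtype=float)
        if current["scale"] is not None:
            pts = pts * current["scale"]
        records.append(
            OutlineSpec(
                points=pts,
                specimen_id=current["id"],
                image=current["image"],
                scale=current["scale"],
            )
        )

    expecting = None  # "lm" or "curve" while reading coordinate lines
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            flush()
            try:
                n_lm = int(line[3:])
            except ValueError:
                raise TPSError(f"line {lineno}: malformed LM= header {line!r}") from None
            current = {
                "n_lm": n_lm,
                "lm_points": [],
                "curve_points": [],
                "declared_curve_points": [],
                "id": "",
                "image": "",
                "scale": None,
            }
            expecting = "lm"
        elif current is None:
            raise TPSError(f"line {lineno}: coordinate data before any LM= header")
        elif upper.startswith("CURVES="):
            expecting = None
        elif upper.startswith("POINTS="):
            try:
                current["declared_curve_points"].append(int(line[7:]))
            except ValueError:
                raise TPSError(f"line {lineno}: malformed POINTS= header") from None
            expecting = "curve"
        elif upper.startswith("ID="):
            current["id"] = line[3:].strip()
        elif upper.startswith("IMAGE="):
            current["image"] = line[6:].strip()
        elif upper.startswith("SCALE="):
            try:
                current["scale"] = float(line[6:])
            except ValueError:
                raise TPSError(f"line {lineno}: non-numeric SCALE=") from None
        elif "=" in line and not line[0].isdigit() and not line[0] in "+-.":
            # unknown KEY= records are tolerated and skipped
            continue
        else:
            xy = _parse_float_pair(line, lineno)
            if expecting == "curve":
                current["curve_points"].append(xy)
            else:
                current["lm_points"].append(xy)
    flush()
    return records


def write_tps(specs, path) -> None:
    """Write outlines as TPS curve records re-readable by :func:`read_tps`."""
    specs = list(specs)
    if not specs:
        raise TPSError("refusing to write an empty TPS file")
    out = []
    for spec in specs:
        pts = spec.points
        if spec.scale is not None:
            pts = pts / spec.scale  # stored back as raw units
        out.append("LM=0")
        out.append("CURVES=1")
        out.append(f"POINTS={len(pts)}")
        for x, y in pts:
            out.append(f"{x:.12g} {y:.12g}")
        if spec.specimen_id:
            out.append(f"ID={spec.specimen_id}")
        if spec.image:
            out.append(f"IMAGE={spec.image}")
        if spec.scale is not None:
            out.append(f"SCALE={spec.scale:.12g}")
    Path(path).write_text("\n".join(out) + "\n")


# ----------------------------------------------------------------------
def read_newick(path_or_text) -> Phylogeny:
    """Read a single rooted tree from a Newick file or string."""
    text = str(path_or_text)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ----------------------------------------------------------------------
@dataclass
class CovariateTable:
    """Species-level ecological covariates keyed by species code.

    Numeric columns: d13C and d15N (per-mil stable-isotope ratios), grnDa and
    grnVa (gill-raker counts on the dorsal/ventral arch), mean_rl (mean
    gill-raker length, mm), GLTL (gut length standardized by total body
    length) and ER (elongation ratio, standard length / body depth).
    Categorical columns: feeding_preference (6 levels) and feeding_mode
    (7 levels).  Missing cells stay as NaN and are dropped per analysis, not
    on load.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if "species_code" not in df.columns:
            raise CovariateError("covariate table needs a species_code column")
        if df["species_code"].duplicated().any():
            raise CovariateError("duplicate species_code rows")
        df = df.set_index("species_code", drop=False)
        for col in NUMERIC_COVARIATES:
            if col in df.columns:
                try:
                    df[col] = pd.to_numeric(df[col])
                except (ValueError, TypeError) as exc:
                    raise CovariateError(f"non-numeric value in column {col}: {exc}")
        for col, levels in CATEGORICAL_COVARIATES.items():
            if col in df.columns:
                bad = set(df[col].dropna()) - set(levels)
                if bad:
                    raise CovariateError(f"unknown {col} label(s): {sorted(bad)}")
        for col in ("ER", "GLTL"):
            if col in df.columns and (df[col].dropna() <= 0).any():
                raise CovariateError(f"{col} must be positive")
        for col in ("grnDa", "grnVa"):
            if col in df.columns and (df[col].dropna() < 0).any():
                raise CovariateError(f"{col} counts must be non-negative")
        self.data = df

    @property
    def species(self) -> list:
        return list(self.data.index)

    def complete_cases(self, columns) -> pd.DataFrame:
        """Rows with no missing value in ``columns`` (pairwise deletion)."""
        cols = list(columns)
        return self.data.dropna(subset=cols)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def read_covariates(path) -> CovariateTable:
    df = pd.read_csv(path)
    return CovariateTable(df)


def write_covariates(table: CovariateTable, path) -> None:
    table.to_csv(path)


# ----------------------------------------------------------------------
def read_config(path) -> dict:
    """Parse a flat ``key = value`` run-configuration file."""
    cfg = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        cfg[key] = value
    return cfg


def get_logger(name: str = "opermorph") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


@contextmanager
def stage_timer(stage: str, logger: logging.Logger | None = None):
    """Log wall-clock duration of a pipeline stage to stderr."""
    logger = logger or get_logger()
    t0 = time.perf_counter()
    logger.info("stage %s: start", stage)
    try:
        yield
    finally:
        logger.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)
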