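"""Core domain types, delimited-text file formats, configuration and logging.

All times are minutes, concentrations kBq/mL unless flagged SUV, distribution
volumes mL/cm^3.  Numeric tables are plain delimited text (comma or tab,
auto-detected from the header line); per-subject metadata travels in ``#
key: value`` comment lines at the top of each file, so the numeric part stays
readable by any CSV tool.

Readers validate invariants and reject malformed input with messages that name
the offending row; they never silently reorder or drop rows.
"""

from __future__ import annotations

import hashlib
import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("pbifpet")

GROUPS = ("healthy", "alcohol", "cannabis")
SESSIONS = ("test", "retest", "baseline", "abstinence")

#: float format used by every writer; round-trips IEEE doubles exactly.
FLOAT_FMT = "%.17g"


def configure_logging(verbose: bool = False) -> None:
    """Route package logs to stderr; one line per pipeline stage."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.DEBUG if verbose else logging.INFO)


def file_checksum(path: str | Path) -> str:
    """Short md5 of a file, echoed in stage logs for provenance."""
    h = hashlib.md5()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:12]


def log_stage(stage: str, **params) -> None:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    log.info("stage=%s %s", stage, kv)


def load_config(path: str | Path) -> dict:
    """Load a YAML config file mapping parameter names to values."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(cfg).__name__}")
    return cfg


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectMeta:
    """Identity and dosimetry for one subject/session.

    weight in kg, injected_activity in MBq, bmi in kg/m^2 (optional; used as
    an ANCOVA covariate in group comparisons).
    """

    subject_id: str
    group: str = "healthy"
    session: str = "test"
    weight: float = float("nan")
    injected_activity: float = float("nan")
    bmi: Optional[float] = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.session not in SESSIONS:
            raise ValueError(f"unknown session {self.session!r}; expected one of {SESSIONS}")
        if np.isfinite(self.weight) and self.weight <= 0:
            raise ValueError(f"weight must be positive, got {self.weight}")
        if np.isfinite(self.injected_activity) and self.injected_activity <= 0:
            raise ValueError(f"injected_activity must be positive, got {self.injected_activity}")
        if self.bmi is not None and self.bmi <= 0:
            raise ValueError(f"bmi must be positive, got {self.bmi}")


@dataclass(frozen=True)
class PlasmaCurve:
    """Arterial plasma parent concentration samples for one subject/session.

    units is ``kBq_per_mL`` for raw measurements or ``SUV`` after
    normalization by injected activity per body weight.  parent_fraction, when
    present, is the fraction of plasma activity attributable to unchanged
    radioligand (metabolite correction has not yet been applied).
    """

    times: np.ndarray
    concentrations: np.ndarray
    units: str = "kBq_per_mL"
    parent_fraction: Optional[np.ndarray] = None
    meta: SubjectMeta = field(default_factory=lambda: SubjectMeta("anon"))

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if self.units not in ("kBq_per_mL", "SUV"):
            raise ValueError(f"unknown units {self.units!r}")
        if t.ndim != 1 or c.shape != t.shape:
            raise ValueError("times and concentrations must be equal-length 1-D arrays")
        if t.size == 0:
            raise ValueError("empty plasma curve")
        if np.any(t < 0):
            raise ValueError("sample times must be >= 0")
        bad = np.where(np.diff(t) <= 0)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"sample times must be strictly increasing; row {i + 1} has "
                f"t={t[i]} followed by t={t[i + 1]}")
        if not np.all(np.isfinite(c)):
            i = int(np.where(~np.isfinite(c))[0][0])
            raise ValueError(f"non-finite concentration at row {i}")
        neg = np.where(c < 0)[0]
        if neg.size:
            i = int(neg[0])
            raise ValueError(f"negative concentration {c[i]} at row {i} (t={t[i]})")
        if self.parent_fraction is not None:
            pf = np.asarray(self.parent_fraction, dtype=float)
            object.__setattr__(self, "parent_fraction", pf)
            if pf.shape != t.shape:
                raise ValueError("parent_fraction length must match times")
            if np.any((pf < 0) | (pf > 1)):
                i = int(np.where((pf < 0) | (pf > 1))[0][0])
                raise ValueError(f"parent_fraction outside [0, 1] at row {i}")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class TACSet:
    """Regional brain time-activity curves with frame timing (PMOD-style).

    values is frames x regions in kBq/mL; frames are contiguous-or-gapped but
    never overlapping, in increasing time order.
    """

    frame_starts: np.ndarray
    frame_ends: np.ndarray
    regions: tuple
    values: np.ndarray
    meta: SubjectMeta = field(default_factory=lambda: SubjectMeta("anon"))

    def __post_init__(self):
        fs = np.asarray(self.frame_starts, dtype=float)
        fe = np.asarray(self.frame_ends, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "frame_starts", fs)
        object.__setattr__(self, "frame_ends", fe)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "regions", tuple(self.regions))
        if fs.ndim != 1 or fe.shape != fs.shape:
            raise ValueError("frame_starts and frame_ends must be equal-length 1-D arrays")
        if np.any(fe <= fs):
            i = int(np.where(fe <= fs)[0][0])
            raise ValueError(f"frame {i} has end {fe[i]} <= start {fs[i]}")
        if np.any(fs[1:] < fe[:-1] - 1e-12):
            i = int(np.where(fs[1:] < fe[:-1] - 1e-12)[0][0])
            raise ValueError(
                f"frames overlap or are out of order: frame {i} ends at {fe[i]} "
                f"but frame {i + 1} starts at {fs[i + 1]}")
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("region names must be unique")
        if v.shape != (fs.size, len(self.regions)):
            raise ValueError(
                f"values shape {v.shape} does not match {fs.size} frames x "
                f"{len(self.regions)} regions")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite TAC value")

    @property
    def frame_mids(self) -> np.ndarray:
        return 0.5 * (self.frame_starts + self.frame_ends)

    @property
    def frame_durations(self) -> np.ndarray:
        return self.frame_ends - self.frame_starts

    def column(self, region: str) -> np.ndarray:
        return self.values[:, self.regions.index(region)]


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

_META_KEYS = {
    "subject_id": str, "group": str, "session": str,
    "weight_kg": float, "injected_MBq": float, "bmi": float,
}


def _meta_to_lines(meta: SubjectMeta, extra: dict | None = None) -> list[str]:
    lines = [
        f"# subject_id: {meta.subject_id}",
        f"# group: {meta.group}",
        f"# session: {meta.session}",
    ]
    if np.isfinite(meta.weight):
        lines.append(f"# weight_kg: {meta.weight!r}")
    if np.isfinite(meta.injected_activity):
        lines.append(f"# injected_MBq: {meta.injected_activity!r}")
    if meta.bmi is not None:
        lines.append(f"# bmi: {meta.bmi!r}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return lines


def _split_header(text: str) -> tuple[dict, str]:
    """Split leading ``# key: value`` comment lines from the numeric table."""
    meta: dict = {}
    body_lines = []
    for line in text.splitlines():
        s = line.strip()
        if s.startswith("#"):
            s = s.lstrip("#").strip()
            if ":" in s:
                k, v = s.split(":", 1)
                meta[k.strip()] = v.strip()
        elif s:
            body_lines.append(line)
    return meta, "\n".join(body_lines)


def _parse_meta(raw: dict) -> SubjectMeta:
    kw = {}
    if "subject_id" in raw:
        kw["subject_id"] = raw["subject_id"]
    else:
        kw["subject_id"] = "anon"
    for src, dst in (("group", "group"), ("session", "session")):
        if src in raw:
            kw[dst] = raw[src]
    if "weight_kg" in raw:
        kw["weight"] = float(raw["weight_kg"])
    if "injected_MBq" in raw:
        kw["injected_activity"] = float(raw["injected_MBq"])
    if "bmi" in raw:
        kw["bmi"] = float(raw["bmi"])
    return SubjectMeta(**kw)


def _detect_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _read_table(body: str, path) -> pd.DataFrame:
    if not body.strip():
        raise ValueError(f"{path}: no data rows")
    sep = _detect_sep(body.splitlines()[0])
    return pd.read_csv(io.StringIO(body), sep=sep, float_precision="round_trip")


_CONC_ALIASES = ("conc_kBq_per_mL", "conc_SUV", "conc")


def read_plasma(path: str | Path) -> PlasmaCurve:
    """Read a plasma parent time-activity curve from delimited text.

    Expected columns: ``time_min``, one of ``conc_kBq_per_mL``/``conc_SUV``/
    ``conc``, and optionally ``parent_fraction``.  Metadata comes from leading
    ``# key: value`` comment lines.
    """
    raw_meta, body = _split_header(Path(path).read_text())
    df = _read_table(body, path)
    if "time_min" not in df.columns:
        raise ValueError(f"{path}: missing required column time_min")
    conc_col = next((c for c in _CONC_ALIASES if c in df.columns), None)
    if conc_col is None:
        raise ValueError(f"{path}: missing concentration column "
                         f"(one of {_CONC_ALIASES})")
    units = raw_meta.get("units",
                         "SUV" if conc_col == "conc_SUV" else "kBq_per_mL")
    pf = df["parent_fraction"].to_numpy() if "parent_fraction" in df.columns else None
    try:
        return PlasmaCurve(
            times=df["time_min"].to_numpy(),
            concentrations=df[conc_col].to_numpy(),
            units=units, parent_fraction=pf, meta=_parse_meta(raw_meta))
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None


def write_plasma(curve: PlasmaCurve, path: str | Path) -> None:
    conc_col = "conc_SUV" if curve.units == "SUV" else "conc_kBq_per_mL"
    cols = {"time_min": curve.times, conc_col: curve.concentrations}
    if curve.parent_fraction is not None:
        cols["parent_fraction"] = curve.parent_fraction
    df = pd.DataFrame(cols)
    lines = _meta_to_lines(curve.meta, {"units": curve.units})
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_tacs(path: str | Path) -> TACSet:
    """Read a regional TAC table: frame_start_min, frame_end_min, one column
    per region."""
    raw_meta, body = _split_header(Path(path).read_text())
    df = _read_table(body, path)
    for col in ("frame_start_min", "frame_end_min"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col}")
    regions = [c for c in df.columns if c not in ("frame_start_min", "frame_end_min")]
    if not regions:
        raise ValueError(f"{path}: no region columns")
    try:
        return TACSet(
            frame_starts=df["frame_start_min"].to_numpy(),
            frame_ends=df["frame_end_min"].to_numpy(),
            regions=regions,
            values=df[regions].to_numpy(),
            meta=_parse_meta(raw_meta))
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None


def write_tacs(tacs: TACSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {"frame_start_min": tacs.frame_starts, "frame_end_min": tacs.frame_ends})
    for j, r in enumerate(tacs.regions):
        df[r] = tacs.values[:, j]
    with open(path, "w") as fh:
        fh.write("\n".join(_meta_to_lines(tacs.meta)) + "\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_pbif(path: str | Path):
    """Read a population-based input function written by :func:`write_pbif`."""
    from .pbif_builder import PBIF
    from .input_function import StandardGrid

    raw_meta, body = _split_header(Path(path).read_text())
    df = _read_table(body, path)
    for col in ("time_min", "mean_SUV", "sd_SUV"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col}")
    excluded = raw_meta.get("excluded_subject") or None
    if excluded in ("", "None"):
        excluded = None
    return PBIF(
        grid=StandardGrid(df["time_min"].to_numpy()),
        mean=df["mean_SUV"].to_numpy(),
        sd=df["sd_SUV"].to_numpy(),
        n=int(raw_meta.get("n", 1)),
        excluded_subject=excluded)


def write_pbif(pbif, path: str | Path) -> None:
    df = pd.DataFrame({"time_min": pbif.grid.times, "mean_SUV": pbif.mean,
                       "sd_SUV": pbif.sd})
    lines = [f"# n: {pbif.n}", f"# excluded_subject: {pbif.excluded_subject or ''}"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_vt_table(path: str | Path):
    """Read a subject x region distribution-volume table."""
    from .reliability_stats import VTTable

    raw_meta, body = _split_header(Path(path).read_text())
    df = _read_table(body, path)
    id_cols = ["subject_id", "group", "session", "weight_kg", "injected_MBq", "bmi"]
    present_ids = [c for c in id_cols if c in df.columns]
    if "subject_id" not in present_ids:
        raise ValueError(f"{path}: missing required column subject_id")
    regions = [c for c in df.columns if c not in id_cols]
    if not regions:
        raise ValueError(f"{path}: no region columns")
    subjects = []
    for _, row in df.iterrows():
        kw = {"subject_id": str(row["subject_id"])}
        if "group" in present_ids:
            kw["group"] = row["group"]
        if "session" in present_ids:
            kw["session"] = row["session"]
        if "weight_kg" in present_ids and np.isfinite(row["weight_kg"]):
            kw["weight"] = float(row["weight_kg"])
        if "injected_MBq" in present_ids and np.isfinite(row["injected_MBq"]):
            kw["injected_activity"] = float(row["injected_MBq"])
        if "bmi" in present_ids and np.isfinite(row["bmi"]):
            kw["bmi"] = float(row["bmi"])
        subjects.append(SubjectMeta(**kw))
    return VTTable(subjects=subjects, regions=regions,
                   values=df[regions].to_numpy(),
                   method=raw_meta.get("method", "logan_full"))


def write_vt_table(table, path: str | Path) -> None:
    df = pd.DataFrame({
        "subject_id": [s.subject_id for s in table.subjects],
        "group": [s.group for s in table.subjects],
        "session": [s.session for s in table.subjects],
        "weight_kg": [s.weight for s in table.subjects],
        "injected_MBq": [s.injected_activity for s in table.subjects],
        "bmi": [np.nan if s.bmi is None else s.bmi for s in table.subjects],
    })
    for j, r in enumerate(table.regions):
        df[r] = table.values[:, j]
    with open(path, "w") as fh:
        fh.write(f"# method: {table.method}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def with_meta(curve: PlasmaCurve, **changes) -> PlasmaCurve:
    """Return a copy of the curve with metadata fields replaced."""
    return replace(curve, meta=replace(curve.meta, **changes))
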