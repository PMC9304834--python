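"""Study/foci table ingestion, Talairach->MNI normalization, sphere radii.

Foci tables are TSV with columns ``study_id, task, n_subjects, space, x, y, z``
plus an optional ``sphere_volume`` (mm^3). Consecutive rows with the same
study entry form one study; the same study id may legitimately recur later in
the table as a separate entry.
"""
from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Focus", "StudyRecord", "FociTable",
    "parse_foci_table", "tal_to_mni", "sphere_radius",
    "TAL2ICBM_SPM", "DEFAULT_SPHERE_RADIUS_MM", "packaged_foci_path",
]

DEFAULT_SPHERE_RADIUS_MM = 3.0
_SPACES = ("TAL", "MNI")
_COORD_LIMIT_MM = 120.0

# Lancaster et al. (2007) icbm_spm2tal affine (MNI/SPM template -> Talairach).
# The TAL -> MNI map used here is its inverse, computed once at import.
ICBM_SPM2TAL = np.array([
    [0.9254, 0.0024, -0.0118, -1.0207],
    [-0.0048, 0.9316, -0.0871, -1.7667],
    [0.0152, 0.0883, 0.8924, 4.0926],
    [0.0, 0.0, 0.0, 1.0],
])
TAL2ICBM_SPM = np.linalg.inv(ICBM_SPM2TAL)


@dataclass(frozen=True)
class Focus:
    x: float
    y: float
    z: float
    space: str = "MNI"
    sphere_volume: float | None = None

    def __post_init__(self):
        if self.space not in _SPACES:
            raise ValueError(f"unknown space token {self.space!r}")
        for c in (self.x, self.y, self.z):
            if not math.isfinite(c):
                raise ValueError("non-finite coordinate")
        if self.sphere_volume is not None and self.sphere_volume <= 0:
            raise ValueError("sphere_volume must be positive")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class StudyRecord:
    study_id: str
    task: str
    n_subjects: int
    foci: tuple[Focus, ...]

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.foci:
            raise ValueError("foci list is empty")
        spaces = {f.space for f in self.foci}
        if len(spaces) > 1:
            raise ValueError(f"study {self.study_id!r} mixes coordinate spaces {spaces}")

    @property
    def space(self) -> str:
        return self.foci[0].space


@dataclass
class FociTable:
    studies: list[StudyRecord] = field(default_factory=list)

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def n_foci(self) -> int:
        return sum(len(s.foci) for s in self.studies)

    def to_mni(self) -> "FociTable":
        """Normalize every study to MNI space (see :func:`tal_to_mni`)."""
        out = []
        for s in self.studies:
            out.append(replace(s, foci=tuple(
                tal_to_mni(f) if f.space == "TAL" else f for f in s.foci)))
        return FociTable(out)

    # -- (de)serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.studies:
            for f in s.foci:
                rows.append({
                    "study_id": s.study_id, "task": s.task,
                    "n_subjects": s.n_subjects, "space": f.space,
                    "x": f.x, "y": f.y, "z": f.z,
                    "sphere_volume": "" if f.sphere_volume is None else f.sphere_volume,
                })
        return pd.DataFrame(rows)

    def to_tsv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, sep="\t", index=False)


def parse_foci_table(source) -> FociTable:
    """Parse a TSV foci table (path, file object, or text) into a FociTable.

    Consecutive rows sharing (study_id, task, n_subjects, space) are grouped
    into one study entry; a repeated study id separated by other rows stays a
    distinct entry, matching how the source table prints a duplicated study.
    """
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    required = {"study_id", "task", "n_subjects", "space", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("no studies")

    studies: list[StudyRecord] = []
    key = None
    foci: list[Focus] = []
    meta = None

    def flush():
        if meta is not None:
            studies.append(StudyRecord(study_id=meta[0], task=meta[1],
                                       n_subjects=meta[2], foci=tuple(foci)))

    for i, row in enumerate(df.itertuples(index=False)):
        space = str(row.space).strip().upper()
        if space in ("TALAIRACH",):
            space = "TAL"
        if space not in _SPACES:
            raise ValueError(f"unknown space token {row.space!r} at row {i}")
        try:
            n = int(str(row.n_subjects).strip())
            x, y, z = (float(str(v).strip()) for v in (row.x, row.y, row.z))
        except ValueError as exc:
            raise ValueError(f"malformed numeric cell at row {i}: {exc}") from exc
        vol = None
        if "sphere_volume" in df.columns:
            raw = str(row.sphere_volume).strip()
            if raw:
                vol = float(raw)
        k = (row.study_id, row.task, n, space)
        if k != key:
            flush()
            key, meta, foci = k, (row.study_id, row.task, n), []
        foci.append(Focus(x=x, y=y, z=z, space=space, sphere_volume=vol))
    flush()
    return FociTable(studies)


def tal_to_mni(f: Focus) -> Focus:
    """Convert a Talairach focus to MNI via the Lancaster tal2icbm (SPM) affine.

    An MNI focus passes through unchanged (with a logged warning).
    """
    if f.space == "MNI":
        logger.warning("tal_to_mni called on MNI focus %s; identity pass-through", (f.x, f.y, f.z))
        return f
    v = TAL2ICBM_SPM @ np.array([f.x, f.y, f.z, 1.0])
    out = Focus(x=float(v[0]), y=float(v[1]), z=float(v[2]), space="MNI",
                sphere_volume=f.sphere_volume)
    for c in (out.x, out.y, out.z):
        if abs(c) > _COORD_LIMIT_MM:
            raise ValueError(f"converted coordinate {c} out of +/-{_COORD_LIMIT_MM} mm range")
    return out


def sphere_radius(f: Focus, default_r: float = DEFAULT_SPHERE_RADIUS_MM) -> float:
    """Radius in mm of the sphere to place at a focus.

    Uses the focus' reported sphere volume when present (r = (3V/4pi)^(1/3)),
    otherwise the configured default radius.
    """
    if default_r <= 0:
        raise ValueError("default_r must be positive")
    if f.sphere_volume is None:
        return float(default_r)
    if f.sphere_volume <= 0:
        raise ValueError("sphere volume must be positive")
    return float((3.0 * f.sphere_volume / (4.0 * math.pi)) ** (1.0 / 3.0))


def packaged_foci_path():
    """Path to the packaged transcription of the meta-analysis input table."""
    return resources.files("salnet.data").joinpath("table1_foci.tsv")
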