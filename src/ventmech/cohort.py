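"""Cohort ingestion: healthy volunteers and repaired-TOF patients.

The bundled fixture transcribes the published per-participant demographic,
CMR-volume and model-derived stress/strain values for 6 healthy (HG) and
12 TOF participants.  TOF patients are split into better (BG) and worse
(WG) post-PVR outcome groups by the median change in RV ejection fraction
(``delta_ef``) six months after pulmonary valve replacement.

Stress values are mean RV max-principal Cauchy stress (kPa) and strain
values mean max-principal Green-Lagrange strain, at the four cardiac time
points begin-filling (bf), end-filling (ef), begin-ejection (be) and
end-ejection (ee), from the one-reference (1G) and two-reference (2G)
model families.  1G models only resolve bf and be; their bf state doubles
as the ee state and their be state as the ef state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "TIME_POINTS",
    "Participant",
    "Cohort",
    "load_cohort",
    "bundled_fixture_path",
    "derive_ef",
    "classify_outcome",
    "cohort_to_long",
]

TIME_POINTS = ("bf", "ef", "be", "ee")

_NUMERIC_COLS = [
    "age_y", "p_max_mmHg", "edv_cm3", "edvi_ml_m2", "esv_cm3", "esvi_ml_m2",
    "ef_pct", "delta_ef_pct",
    "stress_1g_bf", "stress_1g_be",
    "stress_2g_bf", "stress_2g_ef", "stress_2g_be", "stress_2g_ee",
    "strain_1g_bf", "strain_1g_be",
    "strain_2g_bf", "strain_2g_ef", "strain_2g_be", "strain_2g_ee",
]


@dataclass
class Participant:
    """One study participant with demographics and model summaries."""

    id: str
    group: str                      # HG, BG or WG
    sex: str                        # M or F
    age: float                      # years
    p_max: float                    # maximum RV pressure, mmHg
    edv: float                      # end-diastolic volume, cm^3
    esv: float                      # end-systolic volume, cm^3
    ef: float                       # ejection fraction, percent
    edvi: float | None = None       # indexed EDV, ml/m^2 (TOF only)
    esvi: float | None = None
    delta_ef: float | None = None   # post-PVR EF change, percent (TOF only)
    stress_1g: dict = field(default_factory=dict)   # {bf, be} -> kPa
    stress_2g: dict = field(default_factory=dict)   # {bf, ef, be, ee} -> kPa
    strain_1g: dict = field(default_factory=dict)
    strain_2g: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not (0 < self.esv < self.edv):
            raise ValueError(f"{self.id}: need 0 < ESV < EDV, got {self.esv}, {self.edv}")
        if not (0 < self.ef < 100):
            raise ValueError(f"{self.id}: EF out of (0, 100): {self.ef}")
        if self.stress_1g.get("bf") != self.stress_2g.get("bf"):
            raise ValueError(f"{self.id}: 1G and 2G must share the begin-filling stress")
        if self.strain_1g.get("bf") != self.strain_2g.get("bf"):
            raise ValueError(f"{self.id}: 1G and 2G must share the begin-filling strain")
        for name, d in [("stress_1g", self.stress_1g), ("stress_2g", self.stress_2g)]:
            if any(v <= 0 for v in d.values()):
                raise ValueError(f"{self.id}: non-positive value in {name}")
        for name, d in [("strain_1g", self.strain_1g), ("strain_2g", self.strain_2g)]:
            if any(v < 0 for v in d.values()):
                raise ValueError(f"{self.id}: negative value in {name}")


@dataclass
class Cohort:
    participants: list[Participant]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self) -> Iterable[Participant]:
        return iter(self.participants)

    def by_group(self, *groups: str) -> list[Participant]:
        return [p for p in self.participants if p.group in groups]

    @property
    def tof(self) -> list[Participant]:
        return self.by_group("BG", "WG")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            row = {"id": p.id, "group": p.group, "sex": p.sex, "age_y": p.age,
                   "p_max_mmHg": p.p_max, "edv_cm3": p.edv, "edvi_ml_m2": p.edvi,
                   "esv_cm3": p.esv, "esvi_ml_m2": p.esvi, "ef_pct": p.ef,
                   "delta_ef_pct": p.delta_ef}
            for tp in ("bf", "be"):
                row[f"stress_1g_{tp}"] = p.stress_1g[tp]
                row[f"strain_1g_{tp}"] = p.strain_1g[tp]
            for tp in TIME_POINTS:
                row[f"stress_2g_{tp}"] = p.stress_2g[tp]
                row[f"strain_2g_{tp}"] = p.strain_2g[tp]
            rows.append(row)
        return pd.DataFrame(rows)


def bundled_fixture_path() -> Path:
    """Path of the bundled cohort table fixture."""
    return Path(resources.files("ventmech") / "data" / "cohort_tables.csv")


def load_cohort(fixture_path: str | Path | None = None) -> Cohort:
    """Load a cohort from a delimited-text fixture (bundled one by default).

    Raises ``ValueError`` naming the offending row/column on malformed
    numeric cells, and on duplicate participant ids.  Optional fields
    (indexed volumes, delta-EF) may be blank and stay ``None``.
    """
    path = Path(fixture_path) if fixture_path is not None else bundled_fixture_path()
    try:
        df = pd.read_csv(path, comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty or header-less fixture") from exc
    if df.empty:
        raise ValueError(f"{path}: fixture has a header but no participant rows")
    required = {"id", "group", "sex"} | set(_NUMERIC_COLS)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"{path}: duplicate participant ids {dups}")

    participants = []
    for idx, raw in df.iterrows():
        vals = {}
        for col in _NUMERIC_COLS:
            cell = raw[col]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() in ("", "-"):
                vals[col] = None
                continue
            try:
                vals[col] = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed value {cell!r} in row {idx + 1} "
                    f"(id {raw['id']!r}), column {col!r}") from exc
        for col in ("age_y", "p_max_mmHg", "edv_cm3", "esv_cm3", "ef_pct"):
            if vals[col] is None:
                raise ValueError(f"{path}: row {idx + 1} (id {raw['id']!r}) "
                                 f"is missing required column {col!r}")
        p = Participant(
            id=str(raw["id"]), group=str(raw["group"]), sex=str(raw["sex"]),
            age=vals["age_y"], p_max=vals["p_max_mmHg"], edv=vals["edv_cm3"],
            esv=vals["esv_cm3"], ef=vals["ef_pct"], edvi=vals["edvi_ml_m2"],
            esvi=vals["esvi_ml_m2"], delta_ef=vals["delta_ef_pct"],
            stress_1g={"bf": vals["stress_1g_bf"], "be": vals["stress_1g_be"]},
            stress_2g={tp: vals[f"stress_2g_{tp}"] for tp in TIME_POINTS},
            strain_1g={"bf": vals["strain_1g_bf"], "be": vals["strain_1g_be"]},
            strain_2g={tp: vals[f"strain_2g_{tp}"] for tp in TIME_POINTS},
        )
        p.validate()
        participants.append(p)
    return Cohort(participants, provenance=str(path))


def derive_ef(edv: float, esv: float) -> float:
    """Ejection fraction 100 (EDV - ESV) / EDV in percent."""
    if edv <= 0:
        raise ValueError(f"EDV must be positive, got {edv}")
    if not (0 <= esv <= edv):
        raise ValueError(f"need 0 <= ESV <= EDV, got ESV {esv}, EDV {edv}")
    return 100.0 * (edv - esv) / edv


def classify_outcome(cohort: Cohort, threshold: float | str = "median") -> dict[str, str]:
    """Better/worse outcome labels for the TOF participants.

    Patients with ``delta_ef`` strictly above the threshold go to BG, the
    rest to WG.  ``threshold="median"`` uses the median of the TOF
    delta-EF values (midpoint of the central order statistics for even n),
    which reproduces the published even 6/6 split.
    """
    tof = cohort.tof
    missing = [p.id for p in tof if p.delta_ef is None]
    if missing:
        raise ValueError(f"TOF participants missing delta_ef: {missing}")
    values = np.array([p.delta_ef for p in tof], dtype=float)
    thr = float(np.median(values)) if threshold == "median" else float(threshold)
    return {p.id: ("BG" if p.delta_ef > thr else "WG") for p in tof}


def cohort_to_long(cohort: Cohort) -> pd.DataFrame:
    """Tidy long table: participant x time point x model generation x quantity."""
    rows = []
    for p in cohort:
        for gen, stress, strain in [("1G", p.stress_1g, p.strain_1g),
                                    ("2G", p.stress_2g, p.strain_2g)]:
            for tp in TIME_POINTS:
                if tp not in stress:
                    continue
                rows.append({"id": p.id, "group": p.group, "generation": gen,
                             "time_point": tp, "stress_kPa": stress[tp],
                             "strain": strain[tp]})
    return pd.DataFrame(rows)
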