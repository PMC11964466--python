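"""Population estimation: ODI areas + RMCA quartiles -> groups, people,
densities, table totals and phase comparisons.

For a region with Core-Area size A (km²) and catchment quartiles Q1<=Q2<=Q3:

    N_groups(q) = A / q
    N_people(q) = N_groups(q) * group_size        (default 42.5 persons)
    D(q)        = N_people(q) / A  [persons/km²]

Q2 gives the mean estimate; Q1 and Q3 bracket it (smaller catchments imply
more, larger imply fewer groups). Totals are computed from unrounded row
values and rounded once at display time.

Display rounding (half-up): groups to 1 decimal; people to the nearest
integer of the *unrounded* groups × group_size; densities to 3 decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable

import pandas as pd

from .rmca import QuartileSet

QUARTILE_KEYS = ("Q1", "Q2", "Q3")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (ties away from zero), as in the tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_to_hundreds(x: float) -> int:
    """Prose convention for headline people totals (e.g. 14,262 -> 14,300)."""
    return int(round_half_up(x / 100.0) * 100)


@dataclass
class EstimateRow:
    region: str
    odi_km2: float
    quartiles: QuartileSet
    group_size: float = 42.5
    #: unrounded values, keyed Q1/Q2/Q3
    n_groups: dict[str, float] = field(init=False)
    n_people: dict[str, float] = field(init=False)
    density: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.odi_km2 < 0:
            raise ValueError(f"{self.region}: ODI area must be >= 0")
        qs = {"Q1": self.quartiles.q1, "Q2": self.quartiles.q2, "Q3": self.quartiles.q3}
        if min(qs.values()) <= 0:
            raise ValueError(f"{self.region}: quartiles must be positive")
        self.n_groups = {k: self.odi_km2 / q for k, q in qs.items()}
        self.n_people = {k: g * self.group_size for k, g in self.n_groups.items()}
        self.density = {
            k: (p / self.odi_km2 if self.odi_km2 else 0.0)
            for k, p in self.n_people.items()
        }

    def display(self, q: str) -> tuple[float, int, float]:
        """(groups, people, density) rounded as printed."""
        return (
            round_half_up(self.n_groups[q], 1),
            int(round_half_up(self.n_people[q])),
            round_half_up(self.density[q], 3),
        )


def estimate_region(
    odi_km2: float, quartiles: QuartileSet, group_size: float = 42.5, region: str = ""
) -> EstimateRow:
    return EstimateRow(region=region, odi_km2=odi_km2, quartiles=quartiles,
                       group_size=group_size)


@dataclass
class EstimateTable:
    rows: list[EstimateRow]
    tac_area_km2: float = 2_600_000.0
    phase: str = ""
    dataset: str = ""

    @property
    def total_area_km2(self) -> float:
        return sum(r.odi_km2 for r in self.rows)

    def total_groups(self, q: str) -> float:
        return sum(r.n_groups[q] for r in self.rows)

    def total_people(self, q: str) -> float:
        return sum(r.n_people[q] for r in self.rows)

    def core_density(self, q: str) -> float:
        return self.total_people(q) / self.total_area_km2

    def tac_density(self, q: str) -> float:
        return self.total_people(q) / self.tac_area_km2

    def display_totals(self, q: str) -> dict[str, float]:
        return {
            "n_groups": int(round_half_up(self.total_groups(q))),
            "n_people": int(round_half_up(self.total_people(q))),
            "core_density": round_half_up(self.core_density(q), 3),
            "tac_density": round_half_up(self.tac_density(q), 3),
        }

    def people_to_hundreds(self, q: str) -> int:
        return round_to_hundreds(self.total_people(q))

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            for q in QUARTILE_KEYS:
                g, p, d = r.display(q)
                recs.append({
                    "region": r.region, "odi_km2": r.odi_km2, "quartile": q,
                    "rmca_km2": getattr(r.quartiles, q.lower()),
                    "n_raw": r.quartiles.n_raw,
                    "n_groups": g, "n_people": p, "d_population": d,
                })
        return pd.DataFrame(recs)


def summarize(
    rows: Iterable[EstimateRow],
    tac_area_km2: float = 2_600_000.0,
    phase: str = "",
    dataset: str = "",
) -> EstimateTable:
    rows = list(rows)
    if not rows:
        raise ValueError("need at least one estimate row")
    return EstimateTable(rows=rows, tac_area_km2=tac_area_km2, phase=phase, dataset=dataset)


@dataclass
class PhaseComparison:
    people_ratio: dict[str, float]  # per quartile, t2/t1
    area_change_pct: float
    per_region_people_change_pct: dict[str, float]  # Q2-based
    per_region_area_change_pct: dict[str, float]

    def people_per_100km2(self, table: EstimateTable, q: str = "Q2") -> float:
        return 100.0 * table.core_density(q)


def compare_phases(t1: EstimateTable, t2: EstimateTable) -> PhaseComparison:
    """Relative change from table t1 to t2 (same regions required)."""
    r1 = {r.region: r for r in t1.rows}
    r2 = {r.region: r for r in t2.rows}
    if set(r1) != set(r2):
        diff = sorted(set(r1) ^ set(r2))
        raise ValueError(f"region mismatch between tables: {diff}")
    people_ratio = {
        q: t2.total_people(q) / t1.total_people(q) for q in QUARTILE_KEYS
    }
    area_change = 100.0 * (t2.total_area_km2 - t1.total_area_km2) / t1.total_area_km2
    ppl = {
        n: 100.0 * (r2[n].n_people["Q2"] - r1[n].n_people["Q2"]) / r1[n].n_people["Q2"]
        for n in r1
    }
    area = {
        n: 100.0 * (r2[n].odi_km2 - r1[n].odi_km2) / r1[n].odi_km2 for n in r1
    }
    return PhaseComparison(
        people_ratio=people_ratio,
        area_change_pct=area_change,
        per_region_people_change_pct=ppl,
        per_region_area_change_pct=area,
    )


# ---------------------------------------------------------------------------
# packaged reproduction fixture: the printed per-region inputs and the
# printed derived cells of the two phase tables (dataset A)


def _data_path(name: str):
    return resources.files("colognepop.data").joinpath(name)


def load_fixture_inputs(phase: str, dataset: str = "A") -> pd.DataFrame:
    df = pd.read_csv(_data_path("table_inputs.csv"))
    sel = df[(df["phase"] == phase) & (df["dataset"] == dataset)]
    if sel.empty:
        raise ValueError(f"no fixture inputs for phase={phase} dataset={dataset}")
    return sel.reset_index(drop=True)


def load_fixture_expected(phase: str, dataset: str = "A") -> pd.DataFrame:
    df = pd.read_csv(_data_path("table_expected.csv"))
    return df[(df["phase"] == phase) & (df["dataset"] == dataset)].reset_index(drop=True)


def load_counts() -> dict:
    with resources.as_file(_data_path("counts.json")) as p:
        return json.loads(p.read_text(encoding="utf-8"))


def table_from_inputs(
    inputs: pd.DataFrame, group_size: float = 42.5, tac_area_km2: float = 2_600_000.0
) -> EstimateTable:
    rows = []
    for rec in inputs.itertuples(index=False):
        qs = QuartileSet(block=rec.block, q1=rec.q1, q2=rec.q2, q3=rec.q3,
                         n_raw=int(rec.n_raw))
        rows.append(estimate_region(rec.odi_km2, qs, group_size, region=rec.region))
    return summarize(rows, tac_area_km2,
                     phase=str(inputs["phase"].iloc[0]),
                     dataset=str(inputs["dataset"].iloc[0]))


@dataclass
class CellDiff:
    row: str
    quartile: str
    column: str
    computed: float
    printed: float

    def __str__(self) -> str:
        return (f"{self.row} [{self.quartile}] {self.column}: "
                f"computed {self.computed} vs printed {self.printed}")


_PRINT_PRECISION_KM2 = 0.5  # printed quartiles are whole km², so carry ±0.5


def _attainable(printed: float, lo: float, hi: float, ndigits: int) -> bool:
    """Does any value in [lo, hi] round (half-up) to the printed cell?

    The interval is the image of the ±0.5 km² print precision of the input
    quartile; printed cells are accepted when they are attainable under that
    input uncertainty, which is the honest reading of re-deriving a table
    from its own rounded inputs.
    """
    lo, hi = min(lo, hi), max(lo, hi)
    return round_half_up(lo, ndigits) <= printed <= round_half_up(hi, ndigits)


def reproduce_tables(
    phase: str, dataset: str = "A", group_size: float = 42.5,
    tac_area_km2: float = 2_600_000.0,
) -> tuple[EstimateTable, list[CellDiff]]:
    """Recompute one phase table from the packaged printed inputs and diff
    every derived cell against the printed values.

    Returns the computed table and the list of mismatches (empty on success).
    """
    inputs = load_fixture_inputs(phase, dataset)
    table = table_from_inputs(inputs, group_size, tac_area_km2)
    expected = load_fixture_expected(phase, dataset)
    by_region = {r.region: r for r in table.rows}
    eps = _PRINT_PRECISION_KM2
    diffs: list[CellDiff] = []

    def check(row: str, q: str, col: str, computed: float, printed: float,
              lo: float, hi: float, nd: int) -> None:
        if not _attainable(printed, lo, hi, nd):
            diffs.append(CellDiff(row, q, col, round_half_up(computed, nd), printed))

    for rec in expected.itertuples(index=False):
        q = rec.quartile
        if rec.row == "SUM":
            area = table.total_area_km2
            glo = sum(r.odi_km2 / (getattr(r.quartiles, q.lower()) + eps) for r in table.rows)
            ghi = sum(r.odi_km2 / (getattr(r.quartiles, q.lower()) - eps) for r in table.rows)
            check("SUM", q, "n_groups", table.total_groups(q), rec.n_groups, glo, ghi, 0)
            check("SUM", q, "n_people", table.total_people(q), rec.n_people,
                  glo * group_size, ghi * group_size, 0)
            check("SUM", q, "d_population", table.core_density(q), rec.d_population,
                  glo * group_size / area, ghi * group_size / area, 3)
        elif rec.row == "TAC":
            glo = sum(r.odi_km2 / (getattr(r.quartiles, q.lower()) + eps) for r in table.rows)
            ghi = sum(r.odi_km2 / (getattr(r.quartiles, q.lower()) - eps) for r in table.rows)
            check("TAC", q, "d_population", table.tac_density(q), rec.d_population,
                  glo * group_size / tac_area_km2, ghi * group_size / tac_area_km2, 3)
        else:
            r = by_region[rec.row]
            qv = getattr(r.quartiles, q.lower())
            glo, ghi = r.odi_km2 / (qv + eps), r.odi_km2 / (qv - eps)
            check(rec.row, q, "n_groups", r.n_groups[q], rec.n_groups, glo, ghi, 1)
            check(rec.row, q, "n_people", r.n_people[q], rec.n_people,
                  glo * group_size, ghi * group_size, 0)
            check(rec.row, q, "d_population", r.density[q], rec.d_population,
                  glo * group_size / r.odi_km2, ghi * group_size / r.odi_km2, 3)
    return table, diffs
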