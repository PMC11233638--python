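"""Core data model for Purkinje-cell -> cerebellar-nuclear connectivity maps.

A connectivity map records, for each patched CN neuron, which cerebellar
lobules (stimulated at their base, II through X) evoked an IPSC, together
with the evoked amplitudes.  Lobules are grouped into the four transverse
functional zones of the vermis (anterior, central, posterior, nodular) by a
fixed mapping rule; zone-level marginals over all tested cells are the
substrate of the motif analysis.

The module also ships a frozen 75-cell canonical dataset (`build_fixture`)
whose zone-level structure mirrors the study population: 41 cells with at
least one connected lobule, zone marginal counts 13/26/16/13
(anterior/central/posterior/nodular) and exactly three cells receiving
input from all four zones.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


class FormatError(ValueError):
    """A table does not conform to the connectivity file format."""


class Lobule(str, enum.Enum):
    """Cerebellar lobules stimulated at their base, in anatomical order."""

    II = "II"
    III = "III"
    IV_V = "IV/V"
    VI_VII = "VI/VII"
    VIII = "VIII"
    IX = "IX"
    X = "X"

    @property
    def index(self) -> int:
        """Position in the anatomical ordering II < III < ... < X (II = 0)."""
        return _LOBULE_ORDER.index(self)

    @property
    def column(self) -> str:
        """Column name used in tabular files ('/' replaced by '_')."""
        return self.value.replace("/", "_")

    def __lt__(self, other: "Lobule") -> bool:  # anatomical ordering
        return self.index < other.index


_LOBULE_ORDER = [
    Lobule.II,
    Lobule.III,
    Lobule.IV_V,
    Lobule.VI_VII,
    Lobule.VIII,
    Lobule.IX,
    Lobule.X,
]

#: Lobules carried by connectivity tables.  Lobule II is excluded from the
#: tabulated analysis set (several lateral slices do not contain it) but
#: remains a legal label for the zone-mapping rule.
TABLE_LOBULES = [
    Lobule.III,
    Lobule.IV_V,
    Lobule.VI_VII,
    Lobule.VIII,
    Lobule.IX,
    Lobule.X,
]

_COLUMN_TO_LOBULE = {lob.column: lob for lob in _LOBULE_ORDER}


class Zone(str, enum.Enum):
    """Transverse functional zones of the cerebellar vermis."""

    ANTERIOR = "anterior"
    CENTRAL = "central"
    POSTERIOR = "posterior"
    NODULAR = "nodular"


ZONES = [Zone.ANTERIOR, Zone.CENTRAL, Zone.POSTERIOR, Zone.NODULAR]

_ANTERIOR_LOBULES = {Lobule.II, Lobule.III, Lobule.IV_V}


def zones_from_lobules(connected: Iterable[Lobule]) -> frozenset[Zone]:
    """Map a set of connected lobules to the set of transverse zones.

    Rule: lobules II, III and/or IV/V -> anterior; VI/VII -> central;
    VIII, or IX without X -> posterior; X (alone or together with IX) ->
    nodular.  When both IX and X are connected, IX counts toward the
    nodular zone only; VIII contributes to the posterior zone regardless.
    """
    lobules = set(connected)
    for lob in lobules:
        if not isinstance(lob, Lobule):
            raise ValueError(f"unknown lobule label: {lob!r}")
    zones: set[Zone] = set()
    if lobules & _ANTERIOR_LOBULES:
        zones.add(Zone.ANTERIOR)
    if Lobule.VI_VII in lobules:
        zones.add(Zone.CENTRAL)
    if Lobule.VIII in lobules or (Lobule.IX in lobules and Lobule.X not in lobules):
        zones.add(Zone.POSTERIOR)
    if Lobule.X in lobules:
        zones.add(Zone.NODULAR)
    return frozenset(zones)


@dataclass(frozen=True)
class CellConnectivity:
    """Connectivity record for one CN neuron.

    Amplitudes are stored as positive magnitudes in pA regardless of
    recording polarity; an amplitude may only be present for a connected
    lobule.  ``terminal_amplitude_pA`` is the axonal-terminal positive
    control response, when recorded.
    """

    cell_id: str
    connected: Mapping[Lobule, bool]
    amplitude_pA: Mapping[Lobule, float] = field(default_factory=dict)
    terminal_amplitude_pA: float | None = None

    def __post_init__(self) -> None:
        for lob, amp in self.amplitude_pA.items():
            if not self.connected.get(lob, False):
                raise ValueError(
                    f"cell {self.cell_id}: amplitude given for unconnected lobule {lob.value}"
                )
            if amp < 0:
                raise ValueError(f"cell {self.cell_id}: negative amplitude for {lob.value}")
        if self.terminal_amplitude_pA is not None and self.terminal_amplitude_pA < 0:
            raise ValueError(f"cell {self.cell_id}: negative terminal amplitude")

    @property
    def connected_lobules(self) -> frozenset[Lobule]:
        return frozenset(l for l, on in self.connected.items() if on)

    @property
    def zones(self) -> frozenset[Zone]:
        return zones_from_lobules(self.connected_lobules)

    @property
    def is_connected(self) -> bool:
        return len(self.connected_lobules) > 0


@dataclass(frozen=True)
class ConnectivityDataset:
    """Ordered collection of cell records; ``n_total`` counts all tested cells."""

    cells: tuple[CellConnectivity, ...]

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cell_ids in dataset")

    @property
    def n_total(self) -> int:
        return len(self.cells)

    def connected_cells(self) -> tuple[CellConnectivity, ...]:
        """Cells with at least one connected lobule (the analysis subset)."""
        return tuple(c for c in self.cells if c.is_connected)


@dataclass(frozen=True)
class ZoneMarginals:
    """Per-zone connection counts and plug-in probabilities.

    The denominator is the number of all tested cells, including cells
    with no connected lobule.
    """

    counts: Mapping[Zone, int]
    n_total: int

    def __post_init__(self) -> None:
        for z, c in self.counts.items():
            if not 0 <= c <= self.n_total:
                raise ValueError(f"count for {z.value} outside [0, n_total]")

    @property
    def p_zone(self) -> dict[Zone, float]:
        return {z: self.counts[z] / self.n_total for z in ZONES}


def zone_marginals(dataset: ConnectivityDataset) -> ZoneMarginals:
    """Count, per zone, the cells whose mapped zone set contains that zone."""
    if dataset.n_total == 0:
        raise ValueError("empty dataset has no marginals")
    counts = {z: 0 for z in ZONES}
    for cell in dataset.cells:
        for z in cell.zones:
            counts[z] += 1
    return ZoneMarginals(counts=counts, n_total=dataset.n_total)


@dataclass(frozen=True)
class DatasetSummary:
    """Per-cell aggregates and population histograms for a dataset."""

    per_cell: pd.DataFrame           # cell_id, n_lobules, n_zones, mean/sum amplitude
    lobule_histogram: dict[int, int]  # cells by number of connected lobules
    zone_histogram: dict[int, int]    # cells by number of connected zones
    n_total: int
    n_connected: int


def dataset_summary(dataset: ConnectivityDataset) -> DatasetSummary:
    """Per-cell connected counts and amplitude aggregates, plus histograms.

    Cells with zero connections appear in the zero bin of both histograms;
    their amplitude aggregates are reported as missing.
    """
    rows = []
    for cell in dataset.cells:
        lobs = sorted(cell.connected_lobules)
        amps = [cell.amplitude_pA[l] for l in lobs if l in cell.amplitude_pA]
        rows.append(
            {
                "cell_id": cell.cell_id,
                "n_lobules": len(lobs),
                "n_zones": len(cell.zones),
                "mean_amplitude_pA": sum(amps) / len(amps) if amps else None,
                "sum_amplitude_pA": sum(amps) if amps else None,
            }
        )
    per_cell = pd.DataFrame(rows)
    lob_hist: dict[int, int] = {}
    zone_hist: dict[int, int] = {}
    for row in rows:
        lob_hist[row["n_lobules"]] = lob_hist.get(row["n_lobules"], 0) + 1
        zone_hist[row["n_zones"]] = zone_hist.get(row["n_zones"], 0) + 1
    return DatasetSummary(
        per_cell=per_cell,
        lobule_histogram=dict(sorted(lob_hist.items())),
        zone_histogram=dict(sorted(zone_hist.items())),
        n_total=dataset.n_total,
        n_connected=len(dataset.connected_cells()),
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_connectivity_table(
    path: str | Path, lobules: Iterable[Lobule] = TABLE_LOBULES
) -> ConnectivityDataset:
    """Read a comma-separated connectivity table.

    Expected header: ``cell_id`` plus one {0,1} column per lobule
    (III, IV_V, VI_VII, VIII, IX, X) and optional ``amp_<lobule>`` /
    ``amp_terminal`` amplitude columns in pA (empty where unconnected).
    """
    lobules = list(lobules)
    df = pd.read_csv(path, dtype={"cell_id": str})
    if "cell_id" not in df.columns:
        raise FormatError("missing required column: cell_id")
    for lob in lobules:
        if lob.column not in df.columns:
            raise FormatError(f"missing lobule column: {lob.column}")
    cells = []
    for i, row in df.iterrows():
        connected: dict[Lobule, bool] = {}
        amplitudes: dict[Lobule, float] = {}
        for lob in lobules:
            val = row[lob.column]
            if val not in (0, 1):
                raise FormatError(
                    f"row {i}: connectivity value for {lob.column} must be 0 or 1, got {val!r}"
                )
            connected[lob] = bool(val)
            amp_col = f"amp_{lob.column}"
            if amp_col in df.columns and pd.notna(row[amp_col]):
                if not connected[lob]:
                    raise FormatError(
                        f"row {i}: amplitude given for unconnected lobule {lob.column}"
                    )
                amplitudes[lob] = float(row[amp_col])
        terminal = None
        if "amp_terminal" in df.columns and pd.notna(row["amp_terminal"]):
            terminal = float(row["amp_terminal"])
        cells.append(
            CellConnectivity(
                cell_id=str(row["cell_id"]),
                connected=connected,
                amplitude_pA=amplitudes,
                terminal_amplitude_pA=terminal,
            )
        )
    return ConnectivityDataset(cells=tuple(cells))


def write_connectivity_table(
    dataset: ConnectivityDataset,
    path: str | Path,
    lobules: Iterable[Lobule] = TABLE_LOBULES,
) -> None:
    """Write a dataset in the same format `read_connectivity_table` consumes."""
    lobules = list(lobules)
    rows = []
    for cell in dataset.cells:
        row: dict[str, object] = {"cell_id": cell.cell_id}
        for lob in lobules:
            row[lob.column] = int(cell.connected.get(lob, False))
        for lob in lobules:
            amp = cell.amplitude_pA.get(lob)
            row[f"amp_{lob.column}"] = amp if amp is not None else None
        row["amp_terminal"] = cell.terminal_amplitude_pA
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def build_fixture() -> ConnectivityDataset:
    """Load the frozen canonical 75-cell dataset shipped with the package.

    The fixture is a committed data file, byte-identical between calls.  It
    satisfies: 75 cells of which exactly 34 have no connected lobule; zone
    marginal counts anterior 13, central 26, posterior 16, nodular 13;
    exactly 3 four-zone cells; every within-zone lobule pair (III with IV/V,
    VIII with IX) co-occurs in more cells than any cross-zone pair, so that
    average-linkage clustering groups within-zone lobules first.
    Per-connection amplitudes follow the deterministic scheme
    ``40 + 20 * anatomical index`` pA (III -> 60 pA, ..., X -> 160 pA).
    """
    ref = importlib.resources.files("cerebmotif").joinpath(
        "data/fixture_connectivity.csv"
    )
    with importlib.resources.as_file(ref) as path:
        return read_connectivity_table(path)
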