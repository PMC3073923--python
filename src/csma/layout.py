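"""Array plate layouts for cell spot microarrays.

A CSMA plate is a rectangular lattice of printed siRNA/matrix spots.  The
reference geometry is 200 um spots on a 500 um pitch: 108 rows x 36 columns
(3,888 spots) fit in an 18 x 54 mm sub-array, and a four-well plate carries
15,552 spots.  Spots are deposited by a set of solid printing pins (16 in the
reference process); each pin prints a contiguous block of columns, so any
systematic pin-to-pin intensity bias is spatially structured -- the worst case
for downstream normalization and therefore the layout this module produces.

Sample assignment places every library siRNA on one spot, intersperses
negative-control spots equal to ceil(control_fraction x n_targets), and leaves
the remainder flagged empty.  Layouts round-trip through a GAL-style
(GenePix Array List) tab-delimited file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, GeometryError

#: sample_id sentinel for negative-control spots
CONTROL_ID = "NEG_CTRL"
#: sample_id sentinel for unassigned spots
EMPTY_ID = "EMPTY"

#: physical gap between adjacent wells, in units of the spot pitch
_WELL_GAP_PITCHES = 4


@dataclass(frozen=True)
class SpotSpec:
    """One printed spot: physical position plus logical assignment."""

    spot_id: int
    well_id: int
    row: int
    col: int
    x_um: float
    y_um: float
    diameter_um: float
    pin_id: int
    sample_id: str = EMPTY_ID


@dataclass
class ArrayLayout:
    """Spot grid geometry plus per-spot sample/pin assignment for one plate."""

    spots: list[SpotSpec]
    pitch_um: float
    n_wells: int
    plate_name: str = "csma-plate"

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view, one row per spot."""
        return pd.DataFrame([vars(s) for s in self.spots])

    def occupied(self) -> list[SpotSpec]:
        """Spots carrying a target sample or a negative control."""
        return [s for s in self.spots if s.sample_id != EMPTY_ID]

    def validate(self) -> None:
        """Check structural invariants; raise GeometryError on violation."""
        ids = [s.spot_id for s in self.spots]
        if len(set(ids)) != len(ids):
            raise GeometryError("spot_id values are not unique")
        seen: set[tuple[int, int, int]] = set()
        for s in self.spots:
            key = (s.well_id, s.row, s.col)
            if key in seen:
                raise GeometryError(f"duplicate (row, col) within well {s.well_id}")
            seen.add(key)
            if s.x_um < 0 or s.y_um < 0 or s.diameter_um <= 0:
                raise GeometryError(f"spot {s.spot_id} has invalid coordinates")
        # pairwise center distance within a well must respect the pitch
        df = self.to_frame()
        for _, g in df.groupby("well_id"):
            xy = g[["x_um", "y_um"]].to_numpy()
            if len(xy) > 1:
                from scipy.spatial.distance import pdist

                if pdist(xy).min() < self.pitch_um - 1e-6:
                    raise GeometryError("spots closer than the pitch")


@dataclass(frozen=True)
class Sample:
    """One library entry (an siRNA construct or a negative control)."""

    sample_id: str
    target_gene: str = ""
    construct_id: str = ""
    concentration_ng_per_ul: float = 10.0
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.concentration_ng_per_ul <= 0:
            raise ValueError("concentration must be positive")


@dataclass
class SampleSheet:
    """Printable sample library; sample_id must be unique."""

    samples: list[Sample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_id values must be unique")

    @property
    def targets(self) -> list[Sample]:
        return [s for s in self.samples if not s.is_control]

    @classmethod
    def from_gene_list(
        cls,
        genes: Iterable[str],
        constructs_per_gene: int = 2,
        concentration_ng_per_ul: float = 10.0,
    ) -> "SampleSheet":
        """Library with ``constructs_per_gene`` independent siRNAs per gene."""
        samples = [
            Sample(
                sample_id=f"{g}_si{c + 1}",
                target_gene=g,
                construct_id=f"si{c + 1}",
                concentration_ng_per_ul=concentration_ng_per_ul,
            )
            for g in genes
            for c in range(constructs_per_gene)
        ]
        return cls(samples)


def build_layout(
    n_rows: int,
    n_cols: int,
    pitch_um: float,
    diameter_um: float,
    n_wells: int = 1,
    n_pins: int = 1,
    plate_name: str = "csma-plate",
) -> ArrayLayout:
    """Build a rectangular spot lattice, replicated over ``n_wells`` wells.

    The physical origin is the top-left spot center of well 0; +x runs along
    columns, +y along rows.  Wells are laid out side by side along x with a
    small gap.  Pins print contiguous column blocks: column ``c`` is printed
    by pin ``(c * n_pins) // n_cols`` (round-robin when pins do not divide the
    columns evenly).

    Raises
    ------
    GeometryError
        if ``diameter_um >= pitch_um`` (spots would merge) or counts < 1.
    """
    for name, v in [("n_rows", n_rows), ("n_cols", n_cols), ("n_wells", n_wells), ("n_pins", n_pins)]:
        if int(v) < 1:
            raise GeometryError(f"{name} must be >= 1, got {v}")
    if pitch_um <= 0 or diameter_um <= 0:
        raise GeometryError("pitch_um and diameter_um must be positive")
    if diameter_um >= pitch_um:
        raise GeometryError(
            f"spot diameter {diameter_um} um >= pitch {pitch_um} um: spots would merge"
        )

    pitch_um, diameter_um = float(pitch_um), float(diameter_um)
    well_width = (n_cols - 1 + _WELL_GAP_PITCHES) * pitch_um
    spots: list[SpotSpec] = []
    spot_id = 0
    for w in range(n_wells):
        x0 = w * well_width
        for r in range(n_rows):
            for c in range(n_cols):
                spots.append(
                    SpotSpec(
                        spot_id=spot_id,
                        well_id=w,
                        row=r,
                        col=c,
                        x_um=x0 + c * pitch_um,
                        y_um=r * pitch_um,
                        diameter_um=diameter_um,
                        pin_id=(c * n_pins) // n_cols,
                        sample_id=EMPTY_ID,
                    )
                )
                spot_id += 1
    return ArrayLayout(spots=spots, pitch_um=pitch_um, n_wells=n_wells, plate_name=plate_name)


def assign_samples(
    layout: ArrayLayout,
    sheet: SampleSheet,
    control_fraction: float = 0.05,
    seed: int = 0,
) -> ArrayLayout:
    """Randomly place every target sample plus interspersed negative controls.

    The number of control spots is ``ceil(control_fraction * n_targets)`` --
    at least the stated fraction.  Targets land on a seeded uniform shuffle
    of all spots; control spots are interspersed at random positions but
    balanced across printing pins (round-robin over pins, random within a
    pin), so that pin normalization always has anchors on every pin whenever
    there are at least as many controls as pins.  The same seed reproduces
    the assignment exactly.

    Raises
    ------
    CapacityError
        if targets + controls exceed the number of spots.
    """
    if not 0 <= control_fraction < 1:
        raise ValueError("control_fraction must be in [0, 1)")
    targets = sheet.targets
    n_targets = len(targets)
    n_controls = math.ceil(control_fraction * n_targets)
    n_spots = layout.n_spots
    if n_targets + n_controls > n_spots:
        raise CapacityError(
            f"library needs {n_targets + n_controls} spots but layout has {n_spots}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_spots)
    ids: dict[int, str] = {}
    for i, t in enumerate(targets):
        ids[int(order[i])] = t.sample_id
    # controls: round-robin over pins in shuffled pin order, random within pin
    remaining = [int(p) for p in order[n_targets:]]
    by_pin: dict[int, list[int]] = {}
    for pos in remaining:
        by_pin.setdefault(layout.spots[pos].pin_id, []).append(pos)
    pin_cycle = list(rng.permutation(sorted(by_pin)))
    placed = 0
    while placed < n_controls:
        progressed = False
        for pin in pin_cycle:
            if placed >= n_controls:
                break
            if by_pin[pin]:
                ids[by_pin[pin].pop(0)] = CONTROL_ID
                placed += 1
                progressed = True
        if not progressed:  # pragma: no cover - guarded by the capacity check
            break
    assigned = [
        replace(s, sample_id=ids.get(i, EMPTY_ID)) for i, s in enumerate(layout.spots)
    ]
    return ArrayLayout(
        spots=assigned,
        pitch_um=layout.pitch_um,
        n_wells=layout.n_wells,
        plate_name=layout.plate_name,
    )


def reagent_ratio(amount_per_well: float, amount_per_spot: float) -> float:
    """Dimensionless fold-reduction between two positive amounts.

    Works for any like-dimensioned pair (mass, volume, duration): e.g.
    10 ng/well over 50 pg/spot is 200-fold; 12 h over 15 min is 48-fold.
    """
    if amount_per_well <= 0 or amount_per_spot <= 0:
        raise ValueError("amounts must be positive")
    return amount_per_well / amount_per_spot


def percent(part: float, whole: float) -> float:
    """``100 * part / whole`` (e.g. cell types patterned successfully)."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return 100.0 * part / whole


# ---------------------------------------------------------------------------
# GAL-style layout file IO
# ---------------------------------------------------------------------------

_GAL_COLUMNS = ["Block", "Row", "Column", "ID", "Name", "X", "Y", "Dia", "Pin"]


def _fmt(v: float) -> str:
    return f"{v:.6g}"


def write_gal(layout: ArrayLayout, path: str | Path) -> None:
    """Write the layout as a GAL-style tab-delimited file (one Block per well)."""
    lines = [
        "ATF\t1.0",
        "6\t9",
        '"Type=CSMA ArrayList V1.0"',
        f'"PlateName={layout.plate_name}"',
        f'"PitchUm={_fmt(layout.pitch_um)}"',
        f'"Wells={layout.n_wells}"',
        f'"SpotCount={layout.n_spots}"',
        '"Origin=top-left spot center, +x columns, +y rows, um"',
        "\t".join(_GAL_COLUMNS),
    ]
    for s in layout.spots:
        lines.append(
            "\t".join(
                [
                    str(s.well_id + 1),
                    str(s.row + 1),
                    str(s.col + 1),
                    s.sample_id,
                    s.sample_id,
                    _fmt(s.x_um),
                    _fmt(s.y_um),
                    _fmt(s.diameter_um),
                    str(s.pin_id),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gal(path: str | Path) -> ArrayLayout:
    """Read a layout written by :func:`write_gal` (round-trip identical)."""
    text = Path(path).read_text().splitlines()
    meta: dict[str, str] = {}
    header_idx = None
    for i, line in enumerate(text):
        if line.startswith('"') and "=" in line:
            key, val = line.strip('"').split("=", 1)
            meta[key] = val
        elif line.split("\t")[0] == "Block":
            header_idx = i
            break
    if header_idx is None:
        raise ValueError(f"{path}: no GAL table header found")
    spots = []
    for spot_id, line in enumerate(text[header_idx + 1 :]):
        if not line.strip():
            continue
        f = line.split("\t")
        spots.append(
            SpotSpec(
                spot_id=spot_id,
                well_id=int(f[0]) - 1,
                row=int(f[1]) - 1,
                col=int(f[2]) - 1,
                x_um=float(f[5]),
                y_um=float(f[6]),
                diameter_um=float(f[7]),
                pin_id=int(f[8]),
                sample_id=f[3],
            )
        )
    return ArrayLayout(
        spots=spots,
        pitch_um=float(meta.get("PitchUm", "nan")),
        n_wells=int(meta.get("Wells", "1")),
        plate_name=meta.get("PlateName", "csma-plate"),
    )
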