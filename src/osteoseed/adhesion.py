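"""Cell impingement regimes and the attachment ledger.

When a suspended cell reaches a wall, the outcome is decided by the
impingement Weber number

    We = rho_p * d * v_n**2 / sigma,

the ratio of impact inertia to the cell's surface tension: low-energy
contacts stick, intermediate ones rebound inelastically, energetic ones
spread into a film footprint.  The regime thresholds follow the
droplet-impingement literature (stick for We <= 5, rebound for
5 < We < 10, spread for We >= 10) and are config-exposed.  At the
default cell properties (1000 kg/m^3, 25 um, 0.03 N/m) and mm/s impact
speeds We is of order 1e-6, so cells adhere on first contact - the
sticking-dominated picture expected for BMSC recruitment.

Scaffold beams accept attachments only once the marrow has filled the
defect (t >= attach_start); the surrounding trabecular-bone walls of
the defect accept cells for the whole run.  Every attachment is logged
with its position, surface, radial band and sublayer so the
edge-to-middle distribution can be tabulated afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import transport
from .transport import CellPhase, ImpingementEvents

STICK, REBOUND, SPREAD_R = "stick", "rebound", "spread"


@dataclass(frozen=True)
class AdhesionConfig:
    """Impingement-regime thresholds and rebound restitution."""

    we_stick_max: float = 5.0
    we_spread_min: float = 10.0
    restitution: float = 0.9
    attach_start: float = 2.5       # scaffold absorbs cells from here, s
    spread_footprint: float = 2.0   # recorded footprint factor for spread
    enabled: bool = True            # False: every contact reflects elastically

    def __post_init__(self):
        if not 0 < self.we_stick_max <= self.we_spread_min:
            raise ValueError("need 0 < we_stick_max <= we_spread_min")
        if not 0 < self.restitution <= 1:
            raise ValueError("restitution must be in (0, 1]")


def weber_number(cell: CellPhase, v_n) -> np.ndarray | float:
    """Impingement Weber number rho_p d v_n^2 / sigma (v_n >= 0)."""
    if cell.surface_tension <= 0:
        raise ValueError("surface tension must be > 0")
    v = np.asarray(v_n, float)
    if np.any(v < 0):
        raise ValueError("normal velocity must be >= 0")
    we = cell.density * cell.diameter * v * v / cell.surface_tension
    return float(we) if we.ndim == 0 else we


def classify(we, config: AdhesionConfig):
    """Map Weber numbers to 'stick' / 'rebound' / 'spread' (total)."""
    w = np.asarray(we, float)
    out = np.where(w <= config.we_stick_max, STICK,
                   np.where(w < config.we_spread_min, REBOUND, SPREAD_R))
    return str(out) if out.ndim == 0 else out


@dataclass
class AttachmentLedger:
    """Accumulates attachments by surface, radial band and sublayer."""

    n_bands: int = 5
    records: list = field(default_factory=list)

    def log(self, time, x, z, mass, surface, band, layer, beam_id, regime):
        self.records.append(dict(time=float(time), x=float(x), z=float(z),
                                 mass=float(mass), surface=surface,
                                 band=int(band), layer=int(layer),
                                 beam_id=int(beam_id), regime=regime))

    def to_frame(self) -> pd.DataFrame:
        cols = ["time", "x", "z", "mass", "surface", "band", "layer",
                "beam_id", "regime"]
        if not self.records:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame.from_records(self.records)[cols]

    def total_mass(self, surface=None) -> float:
        df = self.to_frame()
        if surface is not None:
            df = df[df.surface == surface]
        return float(df.mass.sum())

    def attached_count(self) -> int:
        return len(self.records)


def resolve(cells: CellPhase, events: ImpingementEvents,
            config: AdhesionConfig, t: float,
            ledger: AttachmentLedger | None = None,
            geometry=None) -> dict:
    """Apply regime outcomes to this step's impingement events.

    stick/spread bind the cell at the contact point (scaffold beams only
    after ``attach_start``; defect boundary always); rebound reflects
    the velocity specularly scaled by the restitution; outlet contacts
    escape.  Returns counts per outcome.
    """
    out = {"stick": 0, "rebound": 0, "spread": 0, "escaped": 0}
    if len(events) == 0:
        return out
    we = weber_number(cells, events.v_normal)
    regime = classify(we, config)
    r = cells.diameter / 2.0
    for j in range(len(events)):
        i = events.index[j]
        kind = events.kind[j]
        n = events.normal[j]
        if kind == "outlet":
            cells.status[i] = transport.ESCAPED
            cells.pos[i] = events.point[j]
            cells.vel[i] = 0.0
            out["escaped"] += 1
            continue
        can_attach = config.enabled and (
            (kind == "boundary") or (kind == "beam"
                                     and t >= config.attach_start))
        reg = regime[j]
        if reg in (STICK, SPREAD_R) and can_attach:
            cells.status[i] = (transport.STUCK if reg == STICK
                               else transport.SPREAD)
            cells.pos[i] = events.point[j]
            cells.vel[i] = 0.0
            out[reg] += 1
            if ledger is not None:
                x, z = events.point[j]
                band = (int(geometry.radial_band(x, ledger.n_bands))
                        if geometry is not None else 0)
                if kind == "beam" and geometry is not None:
                    layer = int(geometry.beam_layers[events.beam_id[j]])
                else:
                    layer = -1
                ledger.log(t, x, z, cells.mass, kind, band, layer,
                           events.beam_id[j], reg)
        else:
            # rebound regime is inelastic; premature scaffold contacts
            # (before attach_start) reflect elastically
            v = cells.vel[i]
            v_ref = v - 2.0 * np.dot(v, n) * n
            e = config.restitution if reg == REBOUND else 1.0
            cells.vel[i] = e * v_ref
            cells.pos[i] = events.point[j] + n * (1e-3 * r)
            out["rebound"] += 1
    return out


def region_density(ledger: AttachmentLedger, geometry,
                   partition: str = "radial") -> pd.DataFrame:
    """Tabulate attached mass by region.

    partition='radial': the five side-to-side bands across the scaffold,
    reporting mean attached mass per beam in each band (beam-averaged,
    scaffold attachments only).  partition='rows': per sublayer.
    partition='surface': scaffold beams vs the defect boundary wall,
    with area-normalized density (the 2D section carries unit depth, so
    areas are perimeter lengths x 1 m).
    """
    df = ledger.to_frame()
    geo = geometry
    if partition == "radial":
        beams = df[df.surface == "beam"]
        half = geo.scaffold.top_diameter / 2.0 * 1e-3
        bands = np.arange(1, ledger.n_bands + 1)
        if len(geo.beam_centers):
            beam_band = geo.radial_band(geo.beam_centers[:, 0],
                                        ledger.n_bands)
        else:
            beam_band = np.zeros(0, int)
        rows = []
        for b in bands:
            n_beams = int(np.sum(beam_band == b))
            mass = float(beams[beams.band == b].mass.sum())
            count = int(len(beams[beams.band == b]))
            rows.append(dict(band=int(b), n_beams=n_beams, count=count,
                             mass=mass,
                             mass_per_beam=mass / n_beams if n_beams else 0.0))
        return pd.DataFrame(rows)
    if partition == "rows":
        beams = df[df.surface == "beam"]
        rows = []
        for layer in range(geo.scaffold.n_sublayers):
            sub = beams[beams.layer == layer]
            n_beams = int(np.sum(geo.beam_layers == layer))
            rows.append(dict(layer=layer, n_beams=n_beams,
                             count=int(len(sub)), mass=float(sub.mass.sum())))
        return pd.DataFrame(rows)
    if partition == "surface":
        beam_mass = float(df[df.surface == "beam"].mass.sum())
        wall_mass = float(df[df.surface == "boundary"].mass.sum())
        # scaffold area: beam-section perimeters; wall area: defect
        # bottom width + two slanted sides (unit depth)
        beam_area = len(geo.beam_centers) * 2 * np.pi * geo.beam_radius
        rb = geo.defect.bottom_diameter / 2.0 * 1e-3
        rt = geo.defect.top_diameter / 2.0 * 1e-3
        slant = np.hypot(rt - rb, geo.depth)
        wall_area = 2 * rb + 2 * slant
        return pd.DataFrame([
            dict(surface="scaffold", mass=beam_mass, area=beam_area,
                 density=beam_mass / beam_area if beam_area else 0.0),
            dict(surface="boundary", mass=wall_mass, area=wall_area,
                 density=wall_mass / wall_area if wall_area else 0.0),
        ])
    raise ValueError(f"unknown partition {partition!r}")
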