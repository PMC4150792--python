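"""Terminator strength as rut-to-termination-zone distance.

Rho-dependent terminators fall into two classes by how far downstream of the
Rho-loading (rut) region their termination zone sits: classical terminators
release within roughly 70-145 nt, whereas weak-recruitment terminators
release several hundred nt downstream.  Under the kinetic model that
distance is set by the commitment (isomerization) time and the dislodging
time, so the observed distance can be inverted -- given assumed polymerase
and Rho translocation speeds -- into an estimate of the mean commitment
time.  No speeds are measured for this system; inferred times are
conditional on the caller-supplied speeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .kinetic_model import InvalidParameterError, _catchup_factor

__all__ = [
    "CoordinateError",
    "InfeasibleParametersError",
    "TerminationZone",
    "distance_stats",
    "classify_terminator",
    "infer_commitment_time",
    "strength_table",
    "DISTANCE_CLASS_THRESHOLD",
]

#: Class boundary (nt): midpoint between the upper end of the classical
#: distance range (145) and the lower end of the long-distance range (385).
DISTANCE_CLASS_THRESHOLD = 265.0


class CoordinateError(ValueError):
    """Termination-zone coordinates are inconsistent with the rut position."""


class InfeasibleParametersError(ValueError):
    """The observed distance cannot be produced by the supplied parameters."""


@dataclass(frozen=True)
class TerminationZone:
    """A termination zone and its upstream rut 3' end, in transcript nt.

    ``zone_start``/``zone_end`` bound the stretch where released transcripts
    end; distances are measured from ``rut_end``, the 3' end of the
    Rho-loading region, because translocation starts there.
    """

    zone_start: float
    zone_end: float
    rut_end: float

    def __post_init__(self) -> None:
        if self.zone_start > self.zone_end:
            raise CoordinateError("zone_start must be <= zone_end")
        if self.rut_end > self.zone_start:
            raise CoordinateError("rut_end must lie upstream of the termination zone")

    @property
    def mean_distance(self) -> float:
        return (self.zone_start + self.zone_end) / 2.0 - self.rut_end


def distance_stats(zone: TerminationZone) -> dict[str, float]:
    """Min / max / mean distance (nt) from the rut 3' end to the zone."""
    return {
        "min": zone.zone_start - zone.rut_end,
        "max": zone.zone_end - zone.rut_end,
        "mean": zone.mean_distance,
    }


def classify_terminator(mean_distance: float,
                        threshold: float = DISTANCE_CLASS_THRESHOLD) -> str:
    """Label a terminator by its rut-to-zone distance.

    ``"tR1-like"`` (classical, short-distance) below ``threshold``;
    ``"trac-like"`` (weak-recruitment, long-distance) at or above it.
    """
    if mean_distance < 0:
        raise CoordinateError("mean_distance must be >= 0")
    return "trac-like" if mean_distance >= threshold else "tR1-like"


def infer_commitment_time(mean_distance: float, rnap_speed: float,
                          rho_speed: float, k_dislodge: float,
                          start_offset: float = 0.0) -> float:
    """Invert the termination-distance model for the mean commitment time.

    Solves the catch-up model's mean-distance formula for E[T]:

        E[T] = [(d - v_rnap/k_dislodge) * (v_rho - v_rnap)/v_rho - offset] / v_rnap.

    Raises :class:`InfeasibleParametersError` when the distance is entirely
    accounted for by the dislodging term (non-positive result).
    """
    factor = _catchup_factor(rnap_speed, rho_speed)
    if not (k_dislodge > 0):
        raise InvalidParameterError("k_dislodge must be > 0")
    catchup = mean_distance - rnap_speed / k_dislodge
    t = (catchup / factor - start_offset) / rnap_speed
    if t <= 0:
        raise InfeasibleParametersError(
            f"distance {mean_distance} nt leaves no positive commitment time "
            f"(dislodging alone explains {rnap_speed / k_dislodge:.3g} nt)")
    return t


def strength_table(zones: pd.DataFrame, rnap_speed: float, rho_speed: float,
                   k_dislodge: float, start_offset: float = 0.0) -> pd.DataFrame:
    """Per-terminator distances, class labels and inferred commitment times.

    ``zones`` needs columns name, rut_end, zone_start, zone_end.  The
    inferred time is NaN where the inversion is infeasible.  All outputs are
    conditional on the supplied speeds.
    """
    required = {"name", "rut_end", "zone_start", "zone_end"}
    missing = required - set(zones.columns)
    if missing:
        raise ValueError(f"zone table missing columns: {sorted(missing)}")
    rows = []
    for rec in zones.itertuples(index=False):
        zone = TerminationZone(zone_start=rec.zone_start, zone_end=rec.zone_end,
                               rut_end=rec.rut_end)
        stats = distance_stats(zone)
        try:
            t_commit = infer_commitment_time(stats["mean"], rnap_speed,
                                             rho_speed, k_dislodge, start_offset)
        except InfeasibleParametersError:
            t_commit = float("nan")
        rows.append({"name": rec.name, "rut_end": rec.rut_end,
                     "zone_start": rec.zone_start, "zone_end": rec.zone_end,
                     "dist_min": stats["min"], "dist_max": stats["max"],
                     "dist_mean": stats["mean"],
                     "terminator_class": classify_terminator(stats["mean"]),
                     "commitment_time_s": t_commit})
    return pd.DataFrame(rows)
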