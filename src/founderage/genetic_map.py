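"""Conversions between physical distance, genetic distance and recombination fraction.

A marker panel around a disease locus is described by :class:`MarkerDef`
records.  Physical distances (Mb from the disease locus) are converted to
genetic distances (cM) with a constant sex-averaged recombination rate
(default 1.64 cM/Mb, the regional estimate used for the TGM1 interval on
14q11), and genetic distances are converted to per-meiosis recombination
fractions with the Kosambi map function, which allows for moderate crossover
interference:

    theta(d) = (1/2) * tanh(2 d)          d in Morgans
    d(theta) = (1/4) * ln((1 + 2 theta) / (1 - 2 theta))

The map function is pluggable wherever a recombination fraction is consumed;
Kosambi is the only one shipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Callable

import pandas as pd

__all__ = [
    "DEFAULT_CM_PER_MB",
    "MapDomainError",
    "MarkerKind",
    "Side",
    "MarkerDef",
    "mb_to_cm",
    "kosambi_theta",
    "kosambi_distance",
    "read_marker_map",
    "write_marker_map",
]

#: Default sex-averaged recombination rate for the region, in cM per Mb.
DEFAULT_CM_PER_MB = 1.64


class MapDomainError(ValueError):
    """Raised for arguments outside the domain of a map-function conversion."""


class MarkerKind(str, Enum):
    SNP = "SNP"
    MICROSATELLITE = "microsatellite"


class Side(str, Enum):
    """Side of the marker relative to the disease locus.

    Estimates depend only on the unsigned distance; the side is kept so that
    panels can be ordered along the chromosome and conserved regions can be
    grown independently in both directions.
    """

    PROXIMAL = "proximal"
    DISTAL = "distal"


def mb_to_cm(d_mb: float, rate: float = DEFAULT_CM_PER_MB) -> float:
    """Convert a physical distance in Mb to a genetic distance in cM.

    Parameters
    ----------
    d_mb
        Physical distance from the disease locus, in megabases (>= 0).
    rate
        Recombination rate in cM per Mb (> 0).
    """
    if d_mb < 0:
        raise MapDomainError(f"physical distance must be >= 0 Mb, got {d_mb}")
    if rate <= 0:
        raise MapDomainError(f"recombination rate must be > 0 cM/Mb, got {rate}")
    return d_mb * rate


def kosambi_theta(d_cm: float) -> float:
    """Kosambi map function: genetic distance (cM) -> recombination fraction.

    theta = tanh(2 d) / 2 with ``d`` in Morgans; strictly increasing, 0 at
    zero distance and approaching 1/2 as distance grows.
    """
    if d_cm < 0:
        raise MapDomainError(f"genetic distance must be >= 0 cM, got {d_cm}")
    # tanh saturates in floats around 7.5 Morgans; keep theta strictly below
    # 1/2 for every finite distance, as the map function requires.
    return min(0.5 * math.tanh(2.0 * d_cm / 100.0), math.nextafter(0.5, 0.0))


def kosambi_distance(theta: float) -> float:
    """Inverse Kosambi map function: recombination fraction -> distance in cM.

    d = (1/4) ln((1 + 2 theta)/(1 - 2 theta)) Morgans.  Round-trips with
    :func:`kosambi_theta` to ~1e-12 relative error.
    """
    if not 0.0 <= theta < 0.5:
        raise MapDomainError(f"recombination fraction must be in [0, 0.5), got {theta}")
    return 25.0 * math.log((1.0 + 2.0 * theta) / (1.0 - 2.0 * theta))


@dataclass(frozen=True)
class MarkerDef:
    """One genotyped locus of the panel.

    Distances are stored unsigned together with an explicit :class:`Side`
    flag; the signed coordinate used for ordering panels is negative on the
    proximal side.  The genetic distance is derived from the physical
    distance (``distance_mb * cm_per_mb``) unless supplied explicitly, in
    which case the supplied map takes precedence.
    """

    name: str
    kind: MarkerKind = MarkerKind.MICROSATELLITE
    distance_mb: float = 0.0
    side: Side = Side.DISTAL
    cm: float | None = None
    cm_per_mb: float = DEFAULT_CM_PER_MB

    def __post_init__(self) -> None:
        if self.distance_mb < 0:
            raise MapDomainError(
                f"marker {self.name}: distance_mb must be >= 0, got {self.distance_mb}"
            )
        if self.cm is not None and self.cm < 0:
            raise MapDomainError(
                f"marker {self.name}: genetic distance must be >= 0 cM, got {self.cm}"
            )

    @property
    def genetic_distance(self) -> float:
        """Genetic distance from the disease locus in cM."""
        if self.cm is not None:
            return self.cm
        return mb_to_cm(self.distance_mb, self.cm_per_mb)

    def theta(self, map_function: Callable[[float], float] = kosambi_theta) -> float:
        """Recombination fraction between marker and locus."""
        return map_function(self.genetic_distance)

    @property
    def signed_position(self) -> float:
        """Signed genetic coordinate (cM) used to order markers along the map."""
        sign = -1.0 if self.side is Side.PROXIMAL else 1.0
        return sign * self.genetic_distance

    def with_rate(self, cm_per_mb: float) -> "MarkerDef":
        """Copy of the marker with a different cM/Mb rate (drops a supplied cM)."""
        return replace(self, cm=None, cm_per_mb=cm_per_mb)


def read_marker_map(
    path: str | Path,
    cm_per_mb: float = DEFAULT_CM_PER_MB,
    locus_position_mb: float | None = None,
) -> list[MarkerDef]:
    """Read a marker map TSV into a list of :class:`MarkerDef`.

    Required columns: ``marker``, ``kind`` and either ``distance_mb`` or
    ``position_mb`` (the latter needs ``locus_position_mb`` to compute the
    distance and the side).  Optional columns: ``side`` and ``cM`` (a supplied
    genetic map overrides the cM/Mb conversion).
    """
    df = pd.read_csv(path, sep="\t", dtype={"marker": str})
    required = {"marker", "kind"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"marker map {path}: missing columns {sorted(missing)}")

    markers: list[MarkerDef] = []
    for i, row in df.iterrows():
        if "distance_mb" in df.columns and not pd.isna(row.get("distance_mb")):
            dist = float(row["distance_mb"])
            side = Side(row["side"]) if "side" in df.columns and not pd.isna(row.get("side")) else Side.DISTAL
        elif "position_mb" in df.columns and not pd.isna(row.get("position_mb")):
            if locus_position_mb is None:
                raise ValueError(
                    f"marker map {path} line {i + 2}: position_mb given but no locus position"
                )
            signed = float(row["position_mb"]) - locus_position_mb
            dist = abs(signed)
            side = Side.PROXIMAL if signed < 0 else Side.DISTAL
        else:
            raise ValueError(f"marker map {path} line {i + 2}: no distance_mb or position_mb")
        cm = None
        if "cM" in df.columns and not pd.isna(row.get("cM")):
            cm = float(row["cM"])
        markers.append(
            MarkerDef(
                name=str(row["marker"]),
                kind=MarkerKind(row["kind"]),
                distance_mb=dist,
                side=side,
                cm=cm,
                cm_per_mb=cm_per_mb,
            )
        )
    return markers


def write_marker_map(markers: list[MarkerDef], path: str | Path) -> None:
    """Write markers as a TSV readable by :func:`read_marker_map`."""
    df = pd.DataFrame(
        {
            "marker": [m.name for m in markers],
            "kind": [m.kind.value for m in markers],
            "distance_mb": [m.distance_mb for m in markers],
            "side": [m.side.value for m in markers],
            "cM": [m.genetic_distance for m in markers],
        }
    )
    df.to_csv(path, sep="\t", index=False)
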