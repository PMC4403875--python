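"""Resolution-binned hydrogen-bond survey tables and Ramachandran maps.

Aggregates per-structure bond classifications into the two standard table
layouts — per-resolution-bin counts with derived percentages, and a
flat category report of the kind used for small curated sets (e.g. the
neutron-diffraction proteins, where amide hydrogens are imaged directly)
— plus a 1 deg x 1 deg Ramachandran occupancy histogram convertible to a
relative pseudo-energy scale by Boltzmann weighting,

    E(bin) = -kT ln(N_bin / N_max),

which is zero at the modal bin and depends only on occupancy ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .hbond_engine import HBond
from .structure_io import ResolutionBin, assign_resolution_bin, default_resolution_bins

__all__ = [
    "SurveyTable",
    "CategoryReport",
    "RamaGrid",
    "BOLTZMANN_KCAL",
    "round_half_up",
    "percentage",
    "tabulate_survey",
    "survey_from_counts",
    "category_report",
    "rama_density",
    "boltzmann_energy",
]

#: Boltzmann constant in kcal/mol/K
BOLTZMANN_KCAL = 0.0019872

SURVEY_COLUMNS = ("total", "alpha", "three_ten", "sheet", "shared")


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), matching printed tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: float, total: float, decimals: int = 2) -> float:
    """round(100 * count / total) half-up; 0 when the total is zero."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, decimals)


@dataclass
class SurveyTable:
    """Per-resolution-bin bond counts and percentages.

    ``counts`` / ``percentages`` are DataFrames indexed by bin label with
    columns total, alpha, three_ten, sheet, shared (percentages omit
    total).  Shared bonds are counted both in their register column and in
    the shared column when ``shared_double_count`` (the default), else
    only in the shared column.
    """

    counts: pd.DataFrame
    percentages: pd.DataFrame
    shared_double_count: bool = True

    def to_tsv(self) -> str:
        merged = self.counts.copy()
        for col in ("alpha", "three_ten", "sheet", "shared"):
            merged[f"{col}_pct"] = self.percentages[col]
        return merged.to_csv(sep="\t", index_label="resolution")


def _bond_counts(bonds: Sequence[HBond], shared_double_count: bool) -> dict[str, int]:
    counts = dict.fromkeys(SURVEY_COLUMNS, 0)
    counts["total"] = len(bonds)
    for bond in bonds:
        if bond.shared:
            counts["shared"] += 1
            if not shared_double_count:
                continue
        if bond.category == "alpha":
            counts["alpha"] += 1
        elif bond.category == "three_ten":
            counts["three_ten"] += 1
        elif bond.category == "sheet":
            counts["sheet"] += 1
    return counts


def tabulate_survey(
    per_structure_results: Sequence[tuple[Optional[float], Sequence[HBond]]],
    bins: Optional[Sequence[ResolutionBin]] = None,
    shared_double_count: bool = True,
) -> SurveyTable:
    """Aggregate (resolution, categorized bonds) pairs into a survey table.

    Structures without a nominal resolution (or outside the binning range)
    are excluded.  Percentages are per-bin shares of the bin total,
    rounded half-up to 2 decimals.
    """
    if bins is None:
        bins = default_resolution_bins()
    rows = {b.label: dict.fromkeys(SURVEY_COLUMNS, 0) for b in bins}
    for resolution, bonds in per_structure_results:
        rbin = assign_resolution_bin(resolution, bins)
        if rbin is None:
            continue
        add = _bond_counts(bonds, shared_double_count)
        row = rows[rbin.label]
        for key in SURVEY_COLUMNS:
            row[key] += add[key]
    return survey_from_counts(rows, shared_double_count=shared_double_count)


def survey_from_counts(
    rows: dict[str, dict[str, int]], shared_double_count: bool = True
) -> SurveyTable:
    """Build a SurveyTable directly from per-bin count dictionaries.

    Accepts the printed layout of the archive survey (total, alpha,
    three_ten, sheet, shared per resolution label) and derives the
    percentage table; used both by :func:`tabulate_survey` and to check
    table arithmetic against published counts.
    """
    counts = pd.DataFrame.from_dict(rows, orient="index")[list(SURVEY_COLUMNS)]
    pct = pd.DataFrame(index=counts.index, columns=SURVEY_COLUMNS[1:], dtype=float)
    for label, row in counts.iterrows():
        for col in SURVEY_COLUMNS[1:]:
            pct.loc[label, col] = percentage(row[col], row["total"], 2)
    return SurveyTable(counts=counts, percentages=pct, shared_double_count=shared_double_count)


@dataclass
class CategoryReport:
    """Flat count/percentage report over one set of categorized bonds.

    Percentages of the grand total are reported to 1 decimal; the
    bifurcated percentage is taken over the helical total (i->i+4 plus
    i->i+3 bonds), as in neutron-set summaries.
    """

    counts: dict[str, int]
    percentages: dict[str, float]
    helical_total: int
    bifurcated: int
    bifurcated_pct_of_helical: float

    def to_tsv(self) -> str:
        lines = ["category\tcount\tpercent"]
        for key, count in self.counts.items():
            lines.append(f"{key}\t{count}\t{self.percentages[key]}")
        lines.append(f"helical_total\t{self.helical_total}\t")
        lines.append(
            f"bifurcated\t{self.bifurcated}\t{self.bifurcated_pct_of_helical}"
        )
        return "\n".join(lines) + "\n"


def category_report(
    bonds: Optional[Sequence[HBond]] = None,
    counts: Optional[dict[str, int]] = None,
    bifurcated: Optional[int] = None,
) -> CategoryReport:
    """Count/percentage report for one categorized bond set.

    Either pass ``bonds`` (counted here, shared flags giving the
    bifurcated tally) or pre-tabulated ``counts`` keyed by category
    (i_to_i4, i_to_i3, sheet, bends, turns, coils, disallowed) with an
    explicit ``bifurcated`` count.
    """
    if counts is None:
        if bonds is None:
            raise ValueError("need bonds or counts")
        counts = {
            "i_to_i4": sum(b.category == "alpha" for b in bonds),
            "i_to_i3": sum(b.category == "three_ten" for b in bonds),
            "sheet": sum(b.category == "sheet" for b in bonds),
            "bends": sum(b.category == "bend" for b in bonds),
            "turns": sum(b.category == "turn" for b in bonds),
            "coils": sum(b.category == "coil" for b in bonds),
            "disallowed": sum(b.category == "disallowed" for b in bonds),
        }
        # each three-centered donor contributes exactly one shared i+3 /
        # i+4 pair, so donors = shared bonds / 2 (robust over merged lists)
        bifurcated = sum(b.shared for b in bonds) // 2
    elif bifurcated is None:
        bifurcated = 0
    total = sum(counts.values())
    percentages = {k: percentage(v, total, 1) for k, v in counts.items()}
    helical_total = counts.get("i_to_i4", 0) + counts.get("i_to_i3", 0)
    return CategoryReport(
        counts=dict(counts),
        percentages=percentages,
        helical_total=helical_total,
        bifurcated=int(bifurcated),
        bifurcated_pct_of_helical=percentage(bifurcated, helical_total, 1),
    )


# -- Ramachandran density ---------------------------------------------------

@dataclass
class RamaGrid:
    """Occupancy (and optionally pseudo-energy) over 1x1-degree (phi, psi) bins.

    ``occupancy[i, j]`` counts pairs with phi in [phi_edges[i],
    phi_edges[i+1]) and likewise psi; edges span [-180, 180].
    """

    bin_size: float
    occupancy: np.ndarray
    energy: Optional[np.ndarray] = None
    temperature: Optional[float] = None

    @property
    def edges(self) -> np.ndarray:
        return np.arange(-180.0, 180.0 + self.bin_size / 2, self.bin_size)

    @property
    def modal_bin(self) -> tuple[float, float]:
        """(phi, psi) lower edge of the highest-occupancy bin."""
        i, j = np.unravel_index(int(np.argmax(self.occupancy)), self.occupancy.shape)
        return (float(self.edges[i]), float(self.edges[j]))

    def to_rows(self, occupied_only: bool = True) -> list[str]:
        rows = ["phi_bin\tpsi_bin\tcount\tenergy"]
        occ = self.occupancy
        for i, j in zip(*np.nonzero(occ if occupied_only else np.ones_like(occ))):
            e = "" if self.energy is None else f"{self.energy[i, j]:.4f}"
            rows.append(f"{self.edges[i]:.0f}\t{self.edges[j]:.0f}\t{int(occ[i, j])}\t{e}")
        return rows


def rama_density(pairs: Sequence[tuple[float, float]], bin_size: float = 1.0) -> RamaGrid:
    """Histogram (phi, psi) pairs into bin_size x bin_size degree bins.

    ``bin_size`` must divide 360 evenly.  Pairs are typically the torsions
    of residues inside assigned helix segments (termini excluded since
    their torsions are undefined).
    """
    if bin_size <= 0 or abs(360.0 / bin_size - round(360.0 / bin_size)) > 1e-9:
        raise ValueError("bin_size must evenly divide 360")
    n = int(round(360.0 / bin_size))
    edges = np.linspace(-180.0, 180.0, n + 1)
    arr = np.asarray(list(pairs), dtype=float).reshape(-1, 2)
    occupancy, _, _ = np.histogram2d(arr[:, 0], arr[:, 1], bins=(edges, edges))
    return RamaGrid(bin_size=float(bin_size), occupancy=occupancy.astype(int))


def boltzmann_energy(grid: RamaGrid, temperature: float = 300.0) -> RamaGrid:
    """Fill the pseudo-energy map E = -kT ln(N/N_max), kcal/mol.

    The modal bin sits at exactly zero; unoccupied bins are +inf.  Scaling
    all occupancies by a common factor leaves the map unchanged.
    """
    n_max = grid.occupancy.max()
    if n_max <= 0:
        raise ValueError("all-zero occupancy grid")
    kt = BOLTZMANN_KCAL * temperature
    with np.errstate(divide="ignore"):
        energy = np.where(
            grid.occupancy > 0,
            -kt * np.log(grid.occupancy / n_max) + 0.0,  # +0.0 avoids -0.0
            np.inf,
        )
    return RamaGrid(
        bin_size=grid.bin_size,
        occupancy=grid.occupancy,
        energy=energy,
        temperature=temperature,
    )
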