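"""Tabular I/O and source-group construction for mixing models.

Reads consumer (tooth) isotope tables, species-level prey source tables and
prey nutrient-composition tables from CSV; pools species into mixing-model
source groups (n-weighted means, full-sample SDs); applies the
muscle+blubber body-mass weighting used for cetacean sources; and converts
atomic elemental ratios to mass concentrations when measured weight-% values
are unavailable.

CSV dialects are UTF-8, comma-separated, with a header row. Column names:

* consumer table: ``individual_id, sex, size_class, row_index, d13C, d15N,
  d34S, cn_atomic`` (optional ``matrix_yield``);
* source table: ``species, tissue, n, d13C_mean, d13C_sd, d15N_mean,
  d15N_sd, d34S_mean, d34S_sd`` plus either ``pC, pN, pS`` mass fractions or
  ``cn_atomic, cs_atomic, ns_atomic`` ratios;
* nutrient table: ``species, pW, pP, pL`` (% wet mass).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ISOTOPE_AXES",
    "ATOMIC_MASS",
    "IsotopeTriple",
    "SpeciesSource",
    "SourceGroup",
    "NutrientComposition",
    "TEFScenario",
    "ConsumerRecord",
    "SchemaError",
    "read_consumer_table",
    "write_consumer_table",
    "read_source_table",
    "read_nutrient_table",
    "read_tef_table",
    "pool_sources",
    "weight_tissues",
    "conc_from_atomic_ratios",
]

#: Fixed axis order used for every vector-valued isotope quantity.
ISOTOPE_AXES = ("d13C", "d15N", "d34S")

#: Standard atomic masses (g/mol) for the three analysed elements.
ATOMIC_MASS = {"C": 12.011, "N": 14.007, "S": 32.06}


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


@dataclass(frozen=True)
class IsotopeTriple:
    """Stable-isotope value triple (d13C vs VPDB, d15N vs AIR, d34S vs VCDT), permil."""

    d13C: float
    d15N: float
    d34S: float

    def __post_init__(self) -> None:
        for axis in ISOTOPE_AXES:
            if not math.isfinite(getattr(self, axis)):
                raise ValueError(f"{axis} must be finite, got {getattr(self, axis)!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.d13C, self.d15N, self.d34S], dtype=float)

    @classmethod
    def from_array(cls, a) -> "IsotopeTriple":
        a = np.asarray(a, dtype=float)
        if a.shape != (3,):
            raise ValueError(f"expected 3 values, got shape {a.shape}")
        return cls(*a)


@dataclass(frozen=True)
class NutrientComposition:
    """Macronutrient composition in % wet mass: water, protein, lipid.

    Carbohydrate (negligible in most marine prey) and ash are absorbed into
    the closure: compositions are renormalised so pW + pP + pL = 100.
    """

    pW: float
    pP: float
    pL: float

    def __post_init__(self) -> None:
        for name in ("pW", "pP", "pL"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")
        if abs(self.pW + self.pP + self.pL - 100.0) > 1e-6:
            raise ValueError(
                f"composition must close to 100, got {self.pW + self.pP + self.pL}"
            )

    @classmethod
    def closed(cls, pW: float, pP: float, pL: float) -> "NutrientComposition":
        """Build a composition renormalising the three parts to sum 100."""
        total = pW + pP + pL
        if total <= 0:
            raise ValueError("composition parts must have positive sum")
        return cls(100.0 * pW / total, 100.0 * pP / total, 100.0 * pL / total)

    def as_array(self) -> np.ndarray:
        """(pP, pL, pW) order: protein, lipid, water."""
        return np.array([self.pP, self.pL, self.pW], dtype=float)


@dataclass(frozen=True)
class TEFScenario:
    """Trophic enrichment factors (diet-to-tissue offsets) with uncertainty."""

    name: str
    delta_mean: IsotopeTriple
    delta_sd: IsotopeTriple

    def __post_init__(self) -> None:
        for axis in ISOTOPE_AXES:
            if getattr(self.delta_sd, axis) < 0:
                raise ValueError(f"TEF SD for {axis} must be >= 0")


@dataclass(frozen=True)
class SpeciesSource:
    """Species-level source summary: isotope mean/SD, n, elemental content."""

    species: str
    tissue: str
    n: int
    iso_mean: IsotopeTriple
    iso_sd: IsotopeTriple
    conc: dict | None = None  # element -> mass fraction in (0, 1)
    atomic_ratios: dict | None = None  # {"cn": ..., "cs": ..., "ns": ...}

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for axis in ISOTOPE_AXES:
            if getattr(self.iso_sd, axis) < 0:
                raise ValueError(f"SD for {axis} must be >= 0")
        if self.conc is not None:
            for e, v in self.conc.items():
                if not (0.0 <= v < 1.0):
                    raise ValueError(f"concentration {e}={v} outside [0, 1)")
        if self.atomic_ratios is not None:
            for k, v in self.atomic_ratios.items():
                if v is not None and v <= 0:
                    raise ValueError(f"atomic ratio {k}={v} must be > 0")


@dataclass(frozen=True)
class SourceGroup:
    """Pooled mixing-model source: n-weighted stats over member species."""

    group_id: int
    label: str
    members: tuple
    n_total: int
    iso_mean: IsotopeTriple
    iso_sd: IsotopeTriple
    conc: dict
    nutrients: NutrientComposition | None = None

    def __post_init__(self) -> None:
        if self.members and self.n_total != sum(m.n for m in self.members):
            raise ValueError("n_total must equal the sum of member n")


@dataclass(frozen=True)
class ConsumerRecord:
    """One serially sampled tissue unit (tooth) from one individual."""

    individual_id: str
    sex: str
    size_class: str
    row_index: int
    iso: IsotopeTriple
    cn_atomic: float
    matrix_yield: float | None = None


_CONSUMER_REQUIRED = [
    "individual_id",
    "sex",
    "size_class",
    "row_index",
    "d13C",
    "d15N",
    "d34S",
    "cn_atomic",
]


def read_consumer_table(path) -> list[ConsumerRecord]:
    """Read a consumer CSV into records ordered by (individual, row_index).

    Raises :class:`SchemaError` naming the first missing column, or a parse
    error with the offending row index for non-numeric isotope values.
    """
    df = pd.read_csv(path)
    for col in _CONSUMER_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"consumer table missing required column {col!r}")
    records = []
    for idx, row in df.iterrows():
        try:
            iso = IsotopeTriple(float(row["d13C"]), float(row["d15N"]), float(row["d34S"]))
            cn = float(row["cn_atomic"])
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"non-numeric value in consumer table row {idx}: {exc}") from exc
        my = row.get("matrix_yield")
        records.append(
            ConsumerRecord(
                individual_id=str(row["individual_id"]),
                sex=str(row["sex"]),
                size_class=str(row["size_class"]),
                row_index=int(row["row_index"]),
                iso=iso,
                cn_atomic=cn,
                matrix_yield=None if my is None or pd.isna(my) else float(my),
            )
        )
    records.sort(key=lambda r: (r.individual_id, r.row_index))
    return records


def write_consumer_table(records, path) -> None:
    """Write consumer records back to CSV (inverse of :func:`read_consumer_table`)."""
    df = pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "sex": [r.sex for r in records],
            "size_class": [r.size_class for r in records],
            "row_index": [r.row_index for r in records],
            "d13C": [r.iso.d13C for r in records],
            "d15N": [r.iso.d15N for r in records],
            "d34S": [r.iso.d34S for r in records],
            "cn_atomic": [r.cn_atomic for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_source_table(path) -> list[SpeciesSource]:
    """Read a species-level source CSV into :class:`SpeciesSource` rows."""
    df = pd.read_csv(path)
    required = ["species", "tissue", "n"] + [
        f"{a}_{s}" for a in ISOTOPE_AXES for s in ("mean", "sd")
    ]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"source table missing required column {col!r}")
    out = []
    for _, row in df.iterrows():
        conc = None
        if all(c in df.columns and not pd.isna(row[c]) for c in ("pC", "pN", "pS")):
            conc = {"C": float(row["pC"]), "N": float(row["pN"]), "S": float(row["pS"])}
        ratios = None
        if "cn_atomic" in df.columns and not pd.isna(row["cn_atomic"]):
            ratios = {
                "cn": float(row["cn_atomic"]),
                "cs": float(row["cs_atomic"]) if "cs_atomic" in df.columns and not pd.isna(row.get("cs_atomic")) else None,
                "ns": float(row["ns_atomic"]) if "ns_atomic" in df.columns and not pd.isna(row.get("ns_atomic")) else None,
            }
        out.append(
            SpeciesSource(
                species=str(row["species"]),
                tissue=str(row["tissue"]),
                n=int(row["n"]),
                iso_mean=IsotopeTriple(*(float(row[f"{a}_mean"]) for a in ISOTOPE_AXES)),
                iso_sd=IsotopeTriple(*(float(row[f"{a}_sd"]) for a in ISOTOPE_AXES)),
                conc=conc,
                atomic_ratios=ratios,
            )
        )
    return out


def read_nutrient_table(path) -> dict[str, NutrientComposition]:
    """Read species -> macronutrient composition, renormalised to close at 100."""
    df = pd.read_csv(path)
    for col in ("species", "pW", "pP", "pL"):
        if col not in df.columns:
            raise SchemaError(f"nutrient table missing required column {col!r}")
    return {
        str(row["species"]): NutrientComposition.closed(
            float(row["pW"]), float(row["pP"]), float(row["pL"])
        )
        for _, row in df.iterrows()
    }


def read_tef_table(path) -> dict[str, TEFScenario]:
    """Read TEF scenarios keyed by name from CSV (columns name, d*_mean, d*_sd)."""
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        name = str(row["name"])
        out[name] = TEFScenario(
            name,
            IsotopeTriple(*(float(row[f"{a}_mean"]) for a in ISOTOPE_AXES)),
            IsotopeTriple(*(float(row[f"{a}_sd"]) for a in ISOTOPE_AXES)),
        )
    return out


def _pooled_stats(ns, means, sds):
    """Full-sample mean and SD from per-member (n, mean, SD).

    The pooled SD reconstructs the total sum of squares as the within-member
    part, sum (n_j - 1) sd_j^2, plus the between-member part,
    sum n_j (mean_j - grand_mean)^2, divided by (N - 1).
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    N = ns.sum()
    grand = float(np.sum(ns * means) / N)
    if N <= 1:
        return grand, float(sds[0]) if len(sds) == 1 else 0.0
    ss_within = float(np.sum((ns - 1) * sds**2))
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    return grand, math.sqrt((ss_within + ss_between) / (N - 1))


def pool_sources(
    members: list[SpeciesSource],
    grouping: dict[str, int],
    labels: dict[int, str] | None = None,
    nutrients: dict[int, NutrientComposition] | None = None,
) -> list[SourceGroup]:
    """Pool species-level sources into mixing-model source groups.

    ``grouping`` maps species name -> group id. Group isotope means are
    n-weighted means of member means; group SDs are full-sample SDs
    reconstructed from member (n, mean, SD); concentrations are n-weighted
    means of member concentrations.
    """
    by_group: dict[int, list[SpeciesSource]] = {}
    for m in members:
        if m.species not in grouping:
            continue
        by_group.setdefault(grouping[m.species], []).append(m)
    if not by_group:
        raise ValueError("grouping matched no members")
    groups = []
    for gid in sorted(by_group):
        mem = by_group[gid]
        for m in mem:
            if m.n > 1 and m.iso_sd is None:
                raise ValueError(f"member {m.species} has n>1 but no SD")
        ns = [m.n for m in mem]
        mean_vals, sd_vals = [], []
        for axis in ISOTOPE_AXES:
            mu, sd = _pooled_stats(
                ns,
                [getattr(m.iso_mean, axis) for m in mem],
                [getattr(m.iso_sd, axis) for m in mem],
            )
            mean_vals.append(mu)
            sd_vals.append(sd)
        conc: dict[str, float] = {}
        if all(m.conc is not None for m in mem):
            for e in mem[0].conc:
                conc[e] = float(np.sum([m.n * m.conc[e] for m in mem]) / np.sum(ns))
        groups.append(
            SourceGroup(
                group_id=gid,
                label=(labels or {}).get(gid, f"group_{gid}"),
                members=tuple(mem),
                n_total=int(np.sum(ns)),
                iso_mean=IsotopeTriple(*mean_vals),
                iso_sd=IsotopeTriple(*sd_vals),
                conc=conc,
                nutrients=(nutrients or {}).get(gid),
            )
        )
    return groups


# Body-mass fraction ranges for dolphin muscle and blubber (literature values);
# defaults are the range midpoints, normalised to sum 1.
DEFAULT_TISSUE_MASS_FRACS = ((0.26 + 0.37) / 2, (0.21 + 0.26) / 2)


def weight_tissues(
    muscle: SpeciesSource,
    blubber: SpeciesSource,
    mass_fracs: tuple[float, float] = DEFAULT_TISSUE_MASS_FRACS,
) -> SpeciesSource:
    """Combine paired muscle and blubber measurements into one whole-prey source.

    Element concentrations combine as plain body-mass-weighted means; isotope
    values combine weighted by mass fraction x element concentration, because
    each tissue's contribution to the consumer's element pool scales with how
    much of the element it carries. When blubber contains no sulfur the d34S
    (value and SD) is taken from muscle alone.
    """
    w = np.asarray(mass_fracs, dtype=float)
    w = w / w.sum()
    if muscle.conc is None or blubber.conc is None:
        raise ValueError("both tissues need element concentrations")
    element_of = {"d13C": "C", "d15N": "N", "d34S": "S"}
    conc = {}
    means, sds = [], []
    for axis in ISOTOPE_AXES:
        e = element_of[axis]
        ce = w[0] * muscle.conc[e] + w[1] * blubber.conc[e]
        conc[e] = float(ce)
        if ce <= 0:
            raise ValueError(f"both tissues have zero {e} concentration")
        tw = np.array([w[0] * muscle.conc[e], w[1] * blubber.conc[e]]) / ce
        if blubber.conc[e] == 0:
            means.append(getattr(muscle.iso_mean, axis))
            sds.append(getattr(muscle.iso_sd, axis))
        else:
            means.append(
                float(tw[0] * getattr(muscle.iso_mean, axis) + tw[1] * getattr(blubber.iso_mean, axis))
            )
            # variance of the weighted mean of two (independent) tissue measurements
            sds.append(
                float(
                    math.sqrt(
                        tw[0] ** 2 * getattr(muscle.iso_sd, axis) ** 2
                        + tw[1] ** 2 * getattr(blubber.iso_sd, axis) ** 2
                    )
                )
            )
    return SpeciesSource(
        species=muscle.species,
        tissue="M,B",
        n=min(muscle.n, blubber.n),
        iso_mean=IsotopeTriple(*means),
        iso_sd=IsotopeTriple(*sds),
        conc=conc,
        atomic_ratios=None,
    )


def conc_from_atomic_ratios(cn: float, cs: float, anchor_pC: float) -> dict[str, float]:
    """Convert atomic C:N and C:S ratios to element mass fractions.

    The carbon mass fraction is anchored at ``anchor_pC``; nitrogen and
    sulfur follow from the atomic ratios and atomic masses:
    pN = pC * M_N / (M_C * C:N), pS = pC * M_S / (M_C * C:S).
    """
    if cn <= 0 or cs <= 0:
        raise ValueError("atomic ratios must be > 0")
    if not (0.0 < anchor_pC < 1.0):
        raise ValueError("anchor_pC must be in (0, 1)")
    pN = anchor_pC * ATOMIC_MASS["N"] / (ATOMIC_MASS["C"] * cn)
    pS = anchor_pC * ATOMIC_MASS["S"] / (ATOMIC_MASS["C"] * cs)
    for name, v in (("pN", pN), ("pS", pS)):
        if v >= 1.0:
            raise ValueError(f"{name}={v} >= 1: anchor inconsistent with ratios")
    return {"C": anchor_pC, "N": pN, "S": pS}
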