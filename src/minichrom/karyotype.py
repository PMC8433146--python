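"""Genome and strain-karyotype models for DT40 chromosome-engineering experiments.

The chicken DT40 B-cell line (standard subclone CL18) has a stable but aneuploid
karyotype: chromosome 2 is trisomic and chromosome 24 is tetrasomic, while the
other chromosomes are disomic.  Telomere-seeding truncation of one of the three
chromosome 2 copies produces derivative strains in which that copy retains only
the q arm, only the p arm plus centromere, or a ~0.7 Mb centromeric
mini-chromosome (0.2 Mb of p-flank plus 0.5 Mb of centromere repeats).

This module encodes those copy-level geometries as explicit interval models that
are shared by the coverage simulator and the copy-number pipeline.  All
coordinates are 0-based, half-open, in base pairs; megabase figures quoted in
strain descriptions convert exactly (52.0 Mb == 52_000_000 bp).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import yaml

MB = 1_000_000

#: p-arm telomere-seeding site (EGFR locus) sits ~0.2 Mb upstream of the
#: centromere; the q-arm site (TPK1 locus) is ~10 kb downstream, below the
#: 10-kb bin resolution, so the q-side break coincides with the centromere end.
P_ARM_OFFSET = 200_000

STRAINS = ("CL18", "Chr2-2", "Chr2_1_1_q", "Chr2_1_1_mini", "Chr2_1_p_q")

Interval = tuple[int, int]

__all__ = [
    "MB",
    "STRAINS",
    "Chromosome",
    "GenomeModel",
    "StrainKaryotype",
    "ConfigurationError",
    "KaryotypeError",
    "build_dt40_genome",
    "make_strain_karyotype",
    "copy_number_at",
    "copy_number_profile",
    "validate_karyotype",
    "genome_to_dict",
    "genome_from_dict",
    "karyotype_to_dict",
    "karyotype_from_dict",
    "read_genome_yaml",
    "write_genome_yaml",
    "read_karyotype_yaml",
    "write_karyotype_yaml",
]


class ConfigurationError(ValueError):
    """Invalid genome or simulation configuration."""


class KaryotypeError(ValueError):
    """Invalid karyotype structure or out-of-domain query."""


@dataclass(frozen=True)
class Chromosome:
    """One chromosome of the control genome.

    Parameters
    ----------
    name : str
        Chromosome identifier, e.g. ``"chr2"``.
    length : int
        Length in base pairs; must be positive.
    control_copies : int
        Copy number in the control (CL18) strain.
    centromere : (int, int), optional
        Half-open centromere interval in base pairs, within ``[0, length)``.
    """

    name: str
    length: int
    control_copies: int = 2
    centromere: Interval | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "length", int(self.length))
        object.__setattr__(self, "control_copies", int(self.control_copies))
        if self.length <= 0:
            raise ConfigurationError(f"{self.name}: length must be positive, got {self.length}")
        if self.control_copies < 1:
            raise ConfigurationError(f"{self.name}: control_copies must be >= 1")
        if self.centromere is not None:
            s, e = (int(x) for x in self.centromere)
            if not (0 <= s < e <= self.length):
                raise ConfigurationError(
                    f"{self.name}: centromere [{s}, {e}) outside chromosome [0, {self.length})"
                )
            object.__setattr__(self, "centromere", (s, e))


@dataclass(frozen=True)
class GenomeModel:
    """Ordered collection of chromosomes with control-strain copy numbers."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate chromosome names: {names}")

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KaryotypeError(f"unknown chromosome {name!r}")

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    def __iter__(self) -> Iterator[Chromosome]:
        return iter(self.chromosomes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)


_DEFAULT_CHROMOSOMES: tuple[tuple[str, int, int, Interval | None], ...] = (
    ("chr1", 196 * MB, 2, None),
    ("chr2", 153 * MB, 3, (52_200_000, 52_700_000)),
    ("chr3", 110 * MB, 2, None),
    ("chr24", 6 * MB, 4, None),
)

_CHROM_FIELDS = ("length", "control_copies", "centromere")


def build_dt40_genome(overrides: Mapping[str, Mapping[str, object]] | None = None) -> GenomeModel:
    """Build the default DT40 (CL18) genome model, optionally overriding geometry.

    The default models four chromosomes: chr1 (196 Mb, the normalization
    reference), chr2 (153 Mb, trisomic, centromere at [52.2, 52.7) Mb), chr3
    (110 Mb) and chr24 (6 Mb, tetrasomic).  ``overrides`` maps chromosome names
    to partial field dictionaries (``length``, ``control_copies``,
    ``centromere``); unknown names add new chromosomes and must include a
    length.
    """
    spec: dict[str, dict[str, object]] = {
        name: {"length": length, "control_copies": copies, "centromere": cen}
        for name, length, copies, cen in _DEFAULT_CHROMOSOMES
    }
    if overrides:
        for name, fields in overrides.items():
            entry = spec.setdefault(
                name, {"length": None, "control_copies": 2, "centromere": None}
            )
            for key, value in dict(fields).items():
                if key not in _CHROM_FIELDS:
                    raise ConfigurationError(f"unknown chromosome field {key!r} for {name!r}")
                entry[key] = value
    chroms = []
    for name, entry in spec.items():
        if entry["length"] is None:
            raise ConfigurationError(f"chromosome {name!r} requires a length")
        cen = entry["centromere"]
        chroms.append(
            Chromosome(
                name=name,
                length=entry["length"],  # type: ignore[arg-type]
                control_copies=entry["control_copies"],  # type: ignore[arg-type]
                centromere=tuple(cen) if cen is not None else None,  # type: ignore[arg-type]
            )
        )
    return GenomeModel(tuple(chroms))


@dataclass(frozen=True)
class StrainKaryotype:
    """Per-chromosome, per-copy retained intervals for one strain.

    ``copies[chrom]`` is a tuple of copies; each copy is a tuple of sorted,
    non-overlapping half-open intervals it retains.  A chromosome copy that is
    entirely absent is simply not listed.
    """

    strain: str
    genome: GenomeModel
    copies: Mapping[str, tuple[tuple[Interval, ...], ...]]


_STRAIN_ALIASES = {
    "cl18": "CL18",
    "dt40cl18": "CL18",
    "chr22": "Chr2-2",
    "chr211q": "Chr2_1_1_q",
    "chr211mini": "Chr2_1_1_mini",
    "chr211minigfp": "Chr2_1_1_mini",
    "chr21pq": "Chr2_1_p_q",
    "chr21pgfpq": "Chr2_1_p_q",
}


def _canonical_strain(name: str) -> str:
    key = re.sub(r"[^0-9a-z]+", "", name.lower())
    if key.startswith("dt40") and key != "dt40cl18":
        key = key[4:]
    try:
        return _STRAIN_ALIASES[key]
    except KeyError:
        raise KaryotypeError(
            f"unknown strain {name!r}; known strains: {', '.join(STRAINS)}"
        ) from None


def make_strain_karyotype(
    strain_name: str,
    genome: GenomeModel | None = None,
    target_chromosome: str = "chr2",
) -> StrainKaryotype:
    """Build the karyotype of one of the five modeled strains.

    CL18 keeps the genome baseline (three full chr2 copies).  Chr2-2 has two
    full copies.  Chr2_1_1_q keeps two full copies plus a q-arm copy retaining
    [p_break, length).  Chr2_1_1_mini keeps two full copies plus the
    mini-chromosome [p_break, q_break).  Chr2_1_p_q keeps one full copy, a
    p+centromere copy [0, q_break) and a q-arm copy [p_break, length), where
    p_break = centromere start - 0.2 Mb and q_break = centromere end.
    """
    genome = genome if genome is not None else build_dt40_genome()
    canonical = _canonical_strain(strain_name)
    target = genome[target_chromosome]
    full: Interval = (0, target.length)

    if canonical in ("CL18", "Chr2-2"):
        n = target.control_copies if canonical == "CL18" else 2
        target_copies: tuple[tuple[Interval, ...], ...] = ((full,),) * n
    else:
        if target.centromere is None:
            raise KaryotypeError(
                f"{target_chromosome} needs a centromere to place truncation breakpoints"
            )
        p_break = target.centromere[0] - P_ARM_OFFSET
        q_break = target.centromere[1]
        if p_break <= 0:
            raise KaryotypeError("p-arm breakpoint falls outside the chromosome")
        if canonical == "Chr2_1_1_q":
            target_copies = ((full,), (full,), ((p_break, target.length),))
        elif canonical == "Chr2_1_1_mini":
            target_copies = ((full,), (full,), ((p_break, q_break),))
        else:  # Chr2_1_p_q
            target_copies = ((full,), ((0, q_break),), ((p_break, target.length),))

    copies: dict[str, tuple[tuple[Interval, ...], ...]] = {}
    for chrom in genome:
        if chrom.name == target_chromosome:
            copies[chrom.name] = target_copies
        else:
            copies[chrom.name] = (((0, chrom.length),),) * chrom.control_copies
    return StrainKaryotype(strain=canonical, genome=genome, copies=copies)


def copy_number_at(karyotype: StrainKaryotype, chromosome: str, position: int) -> int:
    """Number of copies whose retained intervals contain ``position`` (bp)."""
    if chromosome not in karyotype.copies:
        raise KaryotypeError(f"unknown chromosome {chromosome!r} in strain {karyotype.strain}")
    length = karyotype.genome[chromosome].length
    if not 0 <= position < length:
        raise KaryotypeError(f"position {position} outside {chromosome} [0, {length})")
    return sum(
        any(s <= position < e for s, e in copy) for copy in karyotype.copies[chromosome]
    )


def copy_number_profile(
    karyotype: StrainKaryotype, chromosome: str, positions: Sequence[int] | np.ndarray
) -> np.ndarray:
    """Vectorized :func:`copy_number_at` over an array of positions."""
    if chromosome not in karyotype.copies:
        raise KaryotypeError(f"unknown chromosome {chromosome!r} in strain {karyotype.strain}")
    pos = np.asarray(positions, dtype=np.int64)
    length = karyotype.genome[chromosome].length
    if pos.size and (pos.min() < 0 or pos.max() >= length):
        raise KaryotypeError(f"positions outside {chromosome} [0, {length})")
    out = np.zeros(pos.shape, dtype=np.int64)
    for copy in karyotype.copies[chromosome]:
        covered = np.zeros(pos.shape, dtype=bool)
        for s, e in copy:
            covered |= (pos >= s) & (pos < e)
        out += covered
    return out


def validate_karyotype(
    karyotype: StrainKaryotype, genome: GenomeModel | None = None
) -> list[str]:
    """Check type invariants; returns a list of human-readable violations."""
    genome = genome if genome is not None else karyotype.genome
    violations: list[str] = []
    for chrom, copies in karyotype.copies.items():
        if chrom not in genome:
            violations.append(f"{chrom}: not present in genome model")
            continue
        length = genome[chrom].length
        for i, copy in enumerate(copies):
            prev_end: int | None = None
            for s, e in copy:
                if s >= e:
                    violations.append(f"{chrom} copy {i}: empty/inverted interval [{s}, {e})")
                if s < 0 or e > length:
                    violations.append(
                        f"{chrom} copy {i}: interval [{s}, {e}) outside [0, {length})"
                    )
                if prev_end is not None and s < prev_end:
                    violations.append(
                        f"{chrom} copy {i}: intervals overlap or are unsorted at {s}"
                    )
                prev_end = e
    return violations


# ---------------------------------------------------------------------------
# Config-file round trip (YAML)

def genome_to_dict(genome: GenomeModel) -> dict:
    return {
        "chromosomes": [
            {
                "name": c.name,
                "length": c.length,
                "control_copies": c.control_copies,
                "centromere": list(c.centromere) if c.centromere else None,
            }
            for c in genome
        ]
    }


def genome_from_dict(data: Mapping) -> GenomeModel:
    try:
        chroms = tuple(
            Chromosome(
                name=entry["name"],
                length=entry["length"],
                control_copies=entry.get("control_copies", 2),
                centromere=tuple(entry["centromere"]) if entry.get("centromere") else None,
            )
            for entry in data["chromosomes"]
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed genome config: {exc}") from exc
    return GenomeModel(chroms)


def karyotype_to_dict(karyotype: StrainKaryotype) -> dict:
    return {
        "strain": karyotype.strain,
        "genome": genome_to_dict(karyotype.genome),
        "copies": {
            chrom: [[list(iv) for iv in copy] for copy in copies]
            for chrom, copies in karyotype.copies.items()
        },
    }


def karyotype_from_dict(data: Mapping) -> StrainKaryotype:
    genome = genome_from_dict(data["genome"])
    try:
        copies = {
            chrom: tuple(
                tuple((int(s), int(e)) for s, e in copy) for copy in chrom_copies
            )
            for chrom, chrom_copies in data["copies"].items()
        }
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"malformed karyotype config: {exc}") from exc
    return StrainKaryotype(strain=data["strain"], genome=genome, copies=copies)


def write_genome_yaml(genome: GenomeModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(genome_to_dict(genome), fh, sort_keys=False)


def read_genome_yaml(path) -> GenomeModel:
    with open(path) as fh:
        return genome_from_dict(yaml.safe_load(fh))


def write_karyotype_yaml(karyotype: StrainKaryotype, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(karyotype_to_dict(karyotype), fh, sort_keys=False)


def read_karyotype_yaml(path) -> StrainKaryotype:
    with open(path) as fh:
        return karyotype_from_dict(yaml.safe_load(fh))
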