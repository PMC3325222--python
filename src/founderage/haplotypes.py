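"""Phased chromosome panels, trio phasing and conserved-region detection.

The central container is :class:`ChromosomePanel`: a set of phased haplotypes
(disease or control chromosomes) over an ordered marker panel.  Allele labels
are opaque (integer bins for microsatellites, arbitrary strings for SNPs);
no repeat-length semantics are assumed.  Missing calls are allowed and are
excluded from every frequency denominator.

The module also implements the deterministic Mendelian part of trio phasing
(statistical phasing is out of scope; externally phased input is accepted),
detection of the conserved ancestral region shared by all disease
chromosomes around the locus, and the founder-allele rule used by the age
estimators: outside the conserved region the founder allele is taken to be
the most frequent allele among mutation-carrying chromosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import pandas as pd

from .genetic_map import MarkerDef, Side

__all__ = [
    "MISSING_TOKENS",
    "MendelianError",
    "ChromosomePanel",
    "TrioGenotypes",
    "PhasedChild",
    "ConservedRegion",
    "FounderAllele",
    "trio_phase",
    "infer_unsampled_haplotypes",
    "conserved_region",
    "founder_allele",
    "allele_frequency",
    "haplotype_frequency",
    "read_haplotypes_tsv",
    "write_haplotypes_tsv",
    "read_genotypes_tsv",
    "read_vcf_haplotypes",
]

#: Strings interpreted as a missing allele call in text inputs.
MISSING_TOKENS = {".", "", "NA", "na", "None"}


class MendelianError(ValueError):
    """A trio genotype configuration incompatible with Mendelian transmission."""


class FounderAlleleTieWarning(UserWarning):
    """Modal founder allele tied between labels; resolved deterministically."""


def _is_missing(allele: object) -> bool:
    if allele is None or allele is pd.NA:
        return True
    if isinstance(allele, float) and pd.isna(allele):
        return True
    return isinstance(allele, str) and allele in MISSING_TOKENS


def _allele_sort_key(allele: Hashable) -> tuple:
    # Numeric labels sort numerically, everything else lexicographically after.
    try:
        return (0, float(allele), "")  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return (1, 0.0, str(allele))


@dataclass
class ChromosomePanel:
    """Phased haplotypes over an ordered marker panel.

    Parameters
    ----------
    markers
        Marker definitions; stored sorted by signed map position (proximal
        side negative).  Signed positions must be unique.
    data
        One row per chromosome, one column per marker name; values are allele
        labels, missing as ``pd.NA``/``None``.  The index holds chromosome
        identifiers (family.generation.individual plus allele letter, or any
        opaque id).
    group
        ``"disease"`` or ``"control"``.
    """

    markers: list[MarkerDef]
    data: pd.DataFrame
    group: str = "disease"

    def __post_init__(self) -> None:
        order = sorted(self.markers, key=lambda m: m.signed_position)
        positions = [m.signed_position for m in order]
        if len(set(positions)) != len(positions):
            raise ValueError("marker signed positions must be strictly monotone (no ties)")
        names = [m.name for m in order]
        if set(names) != set(self.data.columns):
            raise ValueError(
                f"panel columns {sorted(self.data.columns)} do not match markers {sorted(names)}"
            )
        self.markers = order
        self.data = self.data.loc[:, names].astype(object)
        self.data = self.data.where(~self.data.map(_is_missing), other=pd.NA)
        if self.group == "disease" and len(self.data) < 1:
            raise ValueError("a disease panel must carry at least one haplotype")

    @classmethod
    def from_haplotypes(
        cls,
        markers: Sequence[MarkerDef],
        haplotypes: Iterable[Sequence[Hashable]],
        group: str = "disease",
        ids: Sequence[str] | None = None,
    ) -> "ChromosomePanel":
        """Build a panel from allele vectors given in ``markers`` order."""
        markers = list(markers)
        rows = [list(h) for h in haplotypes]
        for row in rows:
            if len(row) != len(markers):
                raise ValueError("every haplotype needs exactly one allele slot per marker")
        if ids is None:
            ids = [f"{group[0]}{i + 1}" for i in range(len(rows))]
        df = pd.DataFrame(rows, columns=[m.name for m in markers], index=list(ids))
        return cls(markers=markers, data=df, group=group)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def marker(self, name: str) -> MarkerDef:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    def alleles(self, marker: str) -> pd.Series:
        """Non-missing calls at a marker."""
        col = self.data[marker]
        return col[col.notna()]

    def subset(self, chromosome_ids: Sequence[str]) -> "ChromosomePanel":
        return ChromosomePanel(
            markers=list(self.markers), data=self.data.loc[list(chromosome_ids)].copy(), group=self.group
        )


# ---------------------------------------------------------------------------
# frequencies


def allele_frequency(marker: str, panel: ChromosomePanel) -> dict[Hashable, float]:
    """Allele frequency map at ``marker``, over non-missing calls only.

    Frequencies sum to 1 (up to float rounding).  Raises if the panel has no
    non-missing call at the marker.
    """
    calls = panel.alleles(marker)
    if len(calls) == 0:
        raise ValueError(f"no non-missing calls at marker {marker}")
    counts = calls.value_counts()
    total = int(counts.sum())
    return {allele: count / total for allele, count in counts.items()}


def haplotype_frequency(
    vector: Mapping[str, Hashable],
    control: ChromosomePanel,
) -> float:
    """Frequency of an exact haplotype match over a marker interval.

    ``vector`` maps marker names to the required allele.  A missing control
    call counts as a mismatch (the control chromosome cannot be shown to
    carry the haplotype).
    """
    if len(vector) == 0:
        raise ValueError("empty marker interval")
    if control.n == 0:
        raise ValueError("empty control panel")
    match = pd.Series(True, index=control.data.index)
    for marker, allele in vector.items():
        col = control.data[marker]
        match &= col.notna() & (col == allele)
    return float(match.sum()) / control.n


# ---------------------------------------------------------------------------
# conserved region and founder allele


@dataclass(frozen=True)
class ConservedRegion:
    """Maximal contiguous marker interval around the locus shared by all
    disease chromosomes.

    ``markers`` is ordered by signed position; ``shared_alleles`` maps marker
    name to the common allele; ``partial_support`` flags markers where some
    calls were missing (the non-missing ones all agree).  ``genetic_length_cm``
    is the cM span from the outermost proximal to the outermost distal marker
    of the interval (0 for an empty interval).
    """

    markers: tuple[str, ...]
    shared_alleles: Mapping[str, Hashable]
    partial_support: frozenset[str]
    genetic_length_cm: float

    def __contains__(self, marker: str) -> bool:
        return marker in self.markers


def _shared_allele(panel: ChromosomePanel, marker: str) -> tuple[Hashable | None, bool]:
    """(shared allele or None, had-missing-calls) at a marker."""
    col = panel.data[marker]
    calls = col[col.notna()]
    if len(calls) == 0:
        return None, True
    unique = set(calls)
    if len(unique) != 1:
        return None, False
    return next(iter(unique)), len(calls) < len(col)


def conserved_region(disease: ChromosomePanel) -> ConservedRegion:
    """Detect the conserved ancestral haplotype around the disease locus.

    Grows the interval marker by marker from the locus outwards on each side,
    stopping at the first marker where the non-missing disease calls disagree
    (or are all missing).  With fewer than two haplotypes the region is not
    defined.
    """
    if disease.n < 2:
        raise ValueError("conserved region requires at least 2 disease haplotypes")
    proximal = [m for m in disease.markers if m.side is Side.PROXIMAL]
    distal = [m for m in disease.markers if m.side is Side.DISTAL]
    # Walk away from the locus on each side.
    proximal = sorted(proximal, key=lambda m: m.genetic_distance)
    distal = sorted(distal, key=lambda m: m.genetic_distance)

    shared: dict[str, Hashable] = {}
    partial: set[str] = set()
    included: list[MarkerDef] = []
    for side_markers in (proximal, distal):
        for m in side_markers:
            allele, had_missing = _shared_allele(disease, m.name)
            if allele is None:
                break
            shared[m.name] = allele
            if had_missing:
                partial.add(m.name)
            included.append(m)

    included.sort(key=lambda m: m.signed_position)
    if included:
        length = included[-1].signed_position - included[0].signed_position
        # One-sided intervals still span from the locus to the far marker.
        length = max(length, abs(included[0].signed_position), abs(included[-1].signed_position))
    else:
        length = 0.0
    return ConservedRegion(
        markers=tuple(m.name for m in included),
        shared_alleles=shared,
        partial_support=frozenset(partial),
        genetic_length_cm=float(length),
    )


@dataclass(frozen=True)
class FounderAllele:
    allele: Hashable
    p_d: float
    ambiguous: bool = False
    in_conserved_region: bool = False


def founder_allele(
    marker: str,
    disease: ChromosomePanel,
    region: ConservedRegion | None = None,
) -> FounderAllele:
    """Founder allele at a marker and its frequency among disease chromosomes.

    Within the conserved region the shared allele is the founder allele.
    Outside it, the modal allele among mutation carriers is used; ties are
    broken deterministically toward the smallest label, with a warning.
    """
    freqs = allele_frequency(marker, disease)
    if region is not None and marker in region:
        allele = region.shared_alleles[marker]
        return FounderAllele(allele=allele, p_d=freqs[allele], in_conserved_region=True)
    top = max(freqs.values())
    modal = sorted((a for a, f in freqs.items() if f == top), key=_allele_sort_key)
    ambiguous = len(modal) > 1
    if ambiguous:
        warnings.warn(
            f"marker {marker}: modal founder allele tie among {modal}; "
            "using the smallest label",
            FounderAlleleTieWarning,
            stacklevel=2,
        )
    return FounderAllele(allele=modal[0], p_d=top, ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# trio phasing

Genotype = tuple[Hashable, Hashable] | None


@dataclass
class TrioGenotypes:
    """Unphased genotypes of a child and its parents over a marker list.

    Each genotype is an unordered allele pair (tuple of two labels) or
    ``None`` for a missing call.
    """

    markers: list[str]
    child: list[Genotype]
    father: list[Genotype]
    mother: list[Genotype]
    trio_id: str = "trio"

    def __post_init__(self) -> None:
        for name, vec in (("child", self.child), ("father", self.father), ("mother", self.mother)):
            if len(vec) != len(self.markers):
                raise ValueError(f"{name} genotype vector length != number of markers")
            for gt in vec:
                if gt is not None and len(gt) != 2:
                    raise ValueError(f"{name}: genotypes must be allele pairs, got {gt!r}")


@dataclass
class PhasedChild:
    """Result of deterministic trio phasing.

    ``paternal``/``maternal`` hold one allele per marker (``None`` where the
    phase could not be resolved); ``resolved`` flags each marker.
    """

    markers: list[str]
    paternal: list[Hashable | None]
    maternal: list[Hashable | None]
    resolved: list[bool]

    @property
    def resolved_fraction(self) -> float:
        return sum(self.resolved) / len(self.resolved) if self.resolved else 0.0


def _phase_one(
    child: Genotype, father: Genotype, mother: Genotype, marker: str, trio_id: str
) -> tuple[Hashable | None, Hashable | None, bool]:
    if child is None:
        return None, None, False
    a, b = child
    orderings = []
    for pat, mat in {(a, b), (b, a)}:
        if father is not None and pat not in father:
            continue
        if mother is not None and mat not in mother:
            continue
        orderings.append((pat, mat))
    if not orderings:
        # Name the incompatible member for the error message.
        blame = []
        if father is not None and a not in father and b not in father:
            blame.append("father")
        if mother is not None and a not in mother and b not in mother:
            blame.append("mother")
        who = " and ".join(blame) if blame else "trio"
        raise MendelianError(
            f"trio {trio_id}, marker {marker}: child {child} incompatible with {who}"
        )
    if len(orderings) == 1:
        pat, mat = orderings[0]
        return pat, mat, True
    return None, None, False


def trio_phase(trio: TrioGenotypes) -> PhasedChild:
    """Deterministic Mendelian phasing of a child from a trio.

    At each marker the child's alleles are assigned to the paternal and
    maternal haplotypes whenever transmission is unambiguous (a homozygous
    parent or child, or an allele carried by only one parent).  Ambiguous
    markers are flagged unresolved, never guessed.  Mendelian-inconsistent
    markers raise :class:`MendelianError` naming the marker and member.
    """
    paternal: list[Hashable | None] = []
    maternal: list[Hashable | None] = []
    resolved: list[bool] = []
    for i, marker in enumerate(trio.markers):
        pat, mat, ok = _phase_one(trio.child[i], trio.father[i], trio.mother[i], marker, trio.trio_id)
        paternal.append(pat)
        maternal.append(mat)
        resolved.append(ok)
    return PhasedChild(markers=list(trio.markers), paternal=paternal, maternal=maternal, resolved=resolved)


def infer_unsampled_haplotypes(
    parents_and_sibling: TrioGenotypes,
    sibling_carries: tuple[bool, bool],
) -> tuple[PhasedChild, PhasedChild]:
    """Infer the disease haplotypes of an unsampled (e.g. deceased) child.

    Both parents are known mutation carriers; the genotyped non-affected
    sibling is the ``child`` of ``parents_and_sibling``.  ``sibling_carries``
    states, per (paternal, maternal) side, whether the sibling inherited the
    mutation-carrying parental haplotype (known from genotyping the sibling
    at the mutation site).

    Returns the paternal and maternal disease haplotypes as
    :class:`PhasedChild` records with single-sided content (the other side is
    unresolved).  When the sibling carries a parent's mutation, that parent's
    disease haplotype is the one transmitted to the sibling; otherwise it is
    recovered by elimination (the untransmitted parental allele), which
    resolves wherever the parent is homozygous or the transmission is phased.
    """
    sib = trio_phase(parents_and_sibling)
    markers = parents_and_sibling.markers
    out: list[PhasedChild] = []
    for side, (parent_gts, transmitted) in enumerate(
        (
            (parents_and_sibling.father, sib.paternal),
            (parents_and_sibling.mother, sib.maternal),
        )
    ):
        alleles: list[Hashable | None] = []
        flags: list[bool] = []
        carries = sibling_carries[side]
        for i in range(len(markers)):
            gt = parent_gts[i]
            if gt is None:
                alleles.append(None)
                flags.append(False)
                continue
            if gt[0] == gt[1]:
                alleles.append(gt[0])
                flags.append(True)
                continue
            if transmitted[i] is None:
                alleles.append(None)
                flags.append(False)
                continue
            if carries:
                alleles.append(transmitted[i])
            else:
                other = gt[1] if transmitted[i] == gt[0] else gt[0]
                alleles.append(other)
            flags.append(True)
        pat = [None] * len(markers)
        hap = PhasedChild(
            markers=list(markers),
            paternal=alleles if side == 0 else pat,
            maternal=alleles if side == 1 else pat,
            resolved=flags,
        )
        out.append(hap)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# text and VCF input / output


def read_haplotypes_tsv(
    path: str | Path, markers: Sequence[MarkerDef]
) -> dict[str, ChromosomePanel]:
    """Read phased haplotypes (one row per chromosome) into panels by group.

    Expected columns: ``id``, ``group``, then one column per marker name.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("id", "group"):
        if col not in df.columns:
            raise ValueError(f"haplotype table {path}: missing column {col!r}")
    names = [m.name for m in markers]
    missing = set(names) - set(df.columns)
    if missing:
        raise ValueError(f"haplotype table {path}: missing marker columns {sorted(missing)}")
    panels: dict[str, ChromosomePanel] = {}
    for group, sub in df.groupby("group"):
        data = sub.set_index("id")[names]
        panels[str(group)] = ChromosomePanel(markers=list(markers), data=data, group=str(group))
    return panels


def write_haplotypes_tsv(panels: Iterable[ChromosomePanel], path: str | Path) -> None:
    frames = []
    for panel in panels:
        df = panel.data.copy()
        df.insert(0, "group", panel.group)
        df.insert(0, "id", df.index)
        frames.append(df)
    out = pd.concat(frames, axis=0)
    out.to_csv(path, sep="\t", index=False, na_rep=".")


def read_genotypes_tsv(path: str | Path, markers: Sequence[MarkerDef]) -> pd.DataFrame:
    """Read unphased genotypes with two allele columns per marker.

    Expected columns: ``id`` (plus optional ``trio`` and ``role`` columns for
    trio files) and ``<marker>_1``/``<marker>_2`` pairs.  Returns a frame with
    one ``Genotype`` tuple (or ``None``) per marker column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise ValueError(f"genotype table {path}: missing column 'id'")
    out = df[[c for c in ("id", "trio", "role") if c in df.columns]].copy()
    for m in markers:
        c1, c2 = f"{m.name}_1", f"{m.name}_2"
        if c1 not in df.columns or c2 not in df.columns:
            raise ValueError(f"genotype table {path}: missing columns {c1}/{c2}")
        pairs = []
        for a, b in zip(df[c1], df[c2]):
            if a in MISSING_TOKENS or b in MISSING_TOKENS:
                pairs.append(None)
            else:
                pairs.append((a, b))
        out[m.name] = pairs
    return out


def read_vcf_haplotypes(
    path: str | Path,
    markers: Sequence[MarkerDef],
    group: str = "disease",
) -> ChromosomePanel:
    """Read phased SNP genotypes from a VCF into a panel (two chromosomes per
    sample).

    Records are matched to markers by VCF ID; only phased genotypes ("|")
    contribute calls, unphased ones become missing.  Marker map coordinates,
    not VCF positions, remain authoritative for distances.  Requires the
    optional ``cyvcf2`` dependency.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF input requires the optional dependency cyvcf2") from exc

    names = {m.name for m in markers}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: dict[str, dict[str, Hashable]] = {f"{s}.{a}": {} for s in samples for a in "AB"}
    for record in vcf:
        if record.ID not in names:
            continue
        alleles = [record.REF] + list(record.ALT)
        for sample, gt in zip(samples, record.genotypes):
            a0, a1, phased = gt[0], gt[1], bool(gt[2])
            if not phased or a0 < 0 or a1 < 0:
                continue
            calls[f"{sample}.A"][record.ID] = alleles[a0]
            calls[f"{sample}.B"][record.ID] = alleles[a1]
    data = pd.DataFrame.from_dict(calls, orient="index")
    for m in markers:
        if m.name not in data.columns:
            data[m.name] = pd.NA
    return ChromosomePanel(markers=list(markers), data=data[[m.name for m in markers]], group=group)
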