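"""Reading, validation, preprocessing and export of Y-STR haplotype tables.

Y-STR haplotypes are vectors of repeat counts over a forensic marker panel.
Two panel conventions matter downstream:

* ``DYS385a/b`` is a constitutively duplicated locus: two alleles per
  individual with no physical a/b assignment.
* ``DYS389II`` is a composite marker whose reported allele *contains* the
  ``DYS389I`` repeats, so the two markers are not independent; network and
  rho analyses use the difference ``DYS389II - DYS389I`` instead.

The module reads delimited text tables (one row per individual), applies the
rounding rule for intermediate alleles, derives per-analysis views of the
allele matrix, and exports Arlequin ``.arp`` project files.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "MISSING_INT",
    "REGIONS",
    "MarkerPanel",
    "YFILER17",
    "YFILER27",
    "Haplotype",
    "Dataset",
    "ViewMode",
    "AnalysisView",
    "read_haplotype_table",
    "write_haplotype_table",
    "round_intermediate_alleles",
    "make_view",
    "write_arlequin_arp",
    "merge_datasets",
]

#: Sentinel for a missing allele in :class:`Haplotype` dictionaries.
MISSING = None

#: Integer sentinel for a missing allele in :class:`AnalysisView` matrices.
MISSING_INT = -1

#: The five Iberian geographic regions used for regional stratification.
REGIONS = ("Centre", "North", "South", "West", "East")

#: Cell values interpreted as missing on input ('99' is the forensic
#: convention for a null/deleted allele).
DEFAULT_NULL_TOKENS = ("99", "", "NA", "na", "?")


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered set of Y-STR loci with its duplication/containment structure."""

    name: str
    loci: tuple[str, ...]
    duplicated_loci: tuple[str, ...] = ()
    composite_pairs: tuple[tuple[str, str], ...] = ()  # (part, whole)

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("panel locus names must be unique")
        for loc in self.duplicated_loci:
            if loc not in self.loci:
                raise ValueError(f"duplicated locus {loc!r} not in panel")
        for part, whole in self.composite_pairs:
            if part not in self.loci or whole not in self.loci:
                raise ValueError(f"composite pair ({part}, {whole}) not in panel")

    def restrict(self, loci: Sequence[str]) -> "MarkerPanel":
        """Sub-panel keeping only ``loci`` (in this panel's order)."""
        keep = [l for l in self.loci if l in set(loci)]
        kept = set(keep)
        return MarkerPanel(
            name=f"{self.name}[{len(keep)}]",
            loci=tuple(keep),
            duplicated_loci=tuple(l for l in self.duplicated_loci if l in kept),
            composite_pairs=tuple(
                (p, w) for p, w in self.composite_pairs if p in kept and w in kept
            ),
        )


#: The 17-locus AmpFlSTR Yfiler panel.
YFILER17 = MarkerPanel(
    name="Yfiler17",
    loci=(
        "DYS19",
        "DYS389I",
        "DYS389II",
        "DYS390",
        "DYS391",
        "DYS392",
        "DYS393",
        "DYS385a",
        "DYS385b",
        "DYS437",
        "DYS438",
        "DYS439",
        "DYS448",
        "DYS456",
        "DYS458",
        "DYS635",
        "YGATAH4",
    ),
    duplicated_loci=("DYS385a", "DYS385b"),
    composite_pairs=(("DYS389I", "DYS389II"),),
)

#: The 27-locus Yfiler Plus panel (superset of the 17-locus kit).
YFILER27 = MarkerPanel(
    name="YfilerPlus27",
    loci=YFILER17.loci
    + (
        "DYS449",
        "DYS460",
        "DYS481",
        "DYS518",
        "DYS533",
        "DYS570",
        "DYS576",
        "DYS627",
        "DYF387S1a",
        "DYF387S1b",
    ),
    duplicated_loci=("DYS385a", "DYS385b", "DYF387S1a", "DYF387S1b"),
    composite_pairs=(("DYS389I", "DYS389II"),),
)


@dataclass
class Haplotype:
    """One individual's marker → allele map with population/region labels."""

    sample_id: str
    population: str
    alleles: dict[str, Optional[float]]
    region: Optional[str] = None

    def __post_init__(self) -> None:
        if self.region is not None and self.region not in REGIONS:
            raise ValueError(
                f"region {self.region!r} not in the five-region vocabulary {REGIONS}"
            )
        for loc, a in self.alleles.items():
            if a is not None and a <= 0:
                raise ValueError(f"allele {a} at {loc} must be > 0")


@dataclass
class Dataset:
    """A panel plus a list of haplotypes sharing that panel."""

    panel: MarkerPanel
    haplotypes: list[Haplotype]
    provenance: str = ""

    def __post_init__(self) -> None:
        for h in self.haplotypes:
            if not h.population:
                raise ValueError(f"sample {h.sample_id}: empty population label")
            for loc in self.panel.loci:
                h.alleles.setdefault(loc, MISSING)

    def __len__(self) -> int:
        return len(self.haplotypes)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for h in self.haplotypes:
            seen.setdefault(h.population)
        return list(seen)


class ViewMode(Enum):
    """Preprocessing convention applied before a given analysis."""

    PREDICTION = "prediction"  # DYS389II kept as reported (sum of both parts)
    DISTANCE = "distance"  # all loci; DYS385a/b sorted ascending per individual
    NETWORK = "network"  # DYS385a/b dropped; DYS389II -> DYS389II - DYS389I
    RHO = "rho"  # same conventions as NETWORK


@dataclass
class AnalysisView:
    """An integer allele matrix derived from a dataset for one analysis mode.

    ``matrix`` is samples x effective loci with :data:`MISSING_INT` marking
    missing alleles. The source dataset is never modified.
    """

    source: Dataset
    mode: ViewMode
    effective_loci: tuple[str, ...]
    matrix: np.ndarray
    sample_ids: tuple[str, ...]
    populations: tuple[str, ...]
    regions: tuple[Optional[str], ...]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def subset(self, indices: Sequence[int]) -> "AnalysisView":
        idx = list(indices)
        return AnalysisView(
            source=self.source,
            mode=self.mode,
            effective_loci=self.effective_loci,
            matrix=self.matrix[idx],
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            populations=tuple(self.populations[i] for i in idx),
            regions=tuple(self.regions[i] for i in idx),
        )

    def population_indices(self, population: str) -> list[int]:
        return [i for i, p in enumerate(self.populations) if p == population]


def view_from_matrix(
    matrix,
    loci: Sequence[str],
    populations: Sequence[str],
    mode: ViewMode = ViewMode.DISTANCE,
    sample_ids: Optional[Sequence[str]] = None,
    regions: Optional[Sequence[Optional[str]]] = None,
) -> AnalysisView:
    """Build an :class:`AnalysisView` directly from an integer allele matrix.

    Convenience constructor for toy data and simulations where the matrix
    is already in its analysis convention; no view transformation is
    applied. Use :data:`MISSING_INT` for missing entries.
    """
    mat = np.asarray(matrix, dtype=np.int64)
    n = mat.shape[0]
    if sample_ids is None:
        sample_ids = tuple(f"S{i}" for i in range(n))
    if regions is None:
        regions = tuple(None for _ in range(n))
    panel = MarkerPanel(name=f"adhoc{len(loci)}", loci=tuple(loci))
    haps = [
        Haplotype(
            sample_id=sample_ids[i],
            population=populations[i],
            region=regions[i],
            alleles={
                loc: (MISSING if mat[i, j] == MISSING_INT else float(mat[i, j]))
                for j, loc in enumerate(loci)
            },
        )
        for i in range(n)
    ]
    ds = Dataset(panel=panel, haplotypes=haps, provenance="in-memory matrix")
    return AnalysisView(
        source=ds,
        mode=mode,
        effective_loci=tuple(loci),
        matrix=mat,
        sample_ids=tuple(sample_ids),
        populations=tuple(populations),
        regions=tuple(regions),
    )


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_haplotype_table(
    path: str | Path,
    panel: MarkerPanel = YFILER17,
    delimiter: Optional[str] = None,
    null_tokens: Sequence[str] = DEFAULT_NULL_TOKENS,
    provenance: str = "",
) -> Dataset:
    """Read a delimited haplotype table into a :class:`Dataset`.

    The header must name a sample-id column, a population column, optionally
    a region column, and at least the panel's loci. Cells equal to '99',
    empty, or any configured null token become missing. Intermediate alleles
    such as ``13.2`` are preserved at this stage (rounding is a separate,
    explicit step).
    """
    path = Path(path)
    text = path.read_text()
    if delimiter is None:
        delimiter = _sniff_delimiter(text.splitlines()[0])
    rows = list(csv.reader(text.splitlines(), delimiter=delimiter))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = [c.strip() for c in rows[0]]

    def find_col(names: Iterable[str]) -> Optional[int]:
        lower = [c.lower() for c in header]
        for name in names:
            if name in lower:
                return lower.index(name)
        return None

    id_col = find_col(("sampleid", "sample_id", "sample", "id"))
    pop_col = find_col(("population", "pop"))
    reg_col = find_col(("region",))
    if id_col is None or pop_col is None:
        raise ValueError(f"{path}: header must name SampleID and Population columns")

    panel_set = set(panel.loci)
    locus_cols: dict[str, int] = {}
    special = {id_col, pop_col} | ({reg_col} if reg_col is not None else set())
    for j, name in enumerate(header):
        if j in special:
            continue
        if name in panel_set:
            locus_cols[name] = j
        else:
            warnings.warn(f"{path}: ignoring unknown locus column {name!r}")
    missing_loci = panel_set - set(locus_cols)
    if missing_loci:
        raise ValueError(f"{path}: panel loci absent from header: {sorted(missing_loci)}")

    nulls = set(null_tokens)
    haplotypes: list[Haplotype] = []
    seen_ids: set[str] = set()
    for r, row in enumerate(rows[1:], start=2):
        if not any(c.strip() for c in row):
            continue
        sid = row[id_col].strip()
        if sid in seen_ids:
            raise ValueError(f"{path}: duplicate sample_id {sid!r} at row {r}")
        seen_ids.add(sid)
        region = row[reg_col].strip() or None if reg_col is not None else None
        alleles: dict[str, Optional[float]] = {}
        for loc, j in locus_cols.items():
            cell = row[j].strip() if j < len(row) else ""
            if cell in nulls:
                alleles[loc] = MISSING
            else:
                try:
                    alleles[loc] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric allele {cell!r} at row {r}, column {loc}"
                    ) from None
        haplotypes.append(
            Haplotype(sample_id=sid, population=row[pop_col].strip(), region=region, alleles=alleles)
        )
    return Dataset(panel=panel, haplotypes=haplotypes, provenance=provenance or str(path))


def write_haplotype_table(ds: Dataset, path: str | Path, missing_token: str = "99") -> None:
    """Write a dataset back to normalised TSV (inverse of the reader)."""
    path = Path(path)
    has_region = any(h.region is not None for h in ds.haplotypes)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        head = ["SampleID", "Population"] + (["Region"] if has_region else []) + list(ds.panel.loci)
        w.writerow(head)
        for h in ds.haplotypes:
            cells = [h.sample_id, h.population] + ([h.region or ""] if has_region else [])
            for loc in ds.panel.loci:
                a = h.alleles[loc]
                if a is MISSING:
                    cells.append(missing_token)
                elif float(a).is_integer():
                    cells.append(str(int(a)))
                else:
                    cells.append(str(a))
            w.writerow(cells)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def round_intermediate_alleles(ds: Dataset) -> Dataset:
    """Round every non-missing allele to the nearest integer.

    Intermediate alleles (partial repeats such as 13.2) are rounded with
    half-values going away from zero (13.5 → 14).
    """
    out = []
    for h in ds.haplotypes:
        alleles = {
            loc: (MISSING if a is MISSING else float(_round_half_away(a)))
            for loc, a in h.alleles.items()
        }
        out.append(replace(h, alleles=alleles))
    return Dataset(panel=ds.panel, haplotypes=out, provenance=ds.provenance)


def _require_rounded(ds: Dataset) -> None:
    for h in ds.haplotypes:
        for loc, a in h.alleles.items():
            if a is not MISSING and not float(a).is_integer():
                raise ValueError(
                    f"sample {h.sample_id}: allele {a} at {loc} not integral; "
                    "call round_intermediate_alleles first"
                )


def make_view(ds: Dataset, mode: ViewMode) -> AnalysisView:
    """Derive the integer allele matrix for one analysis mode.

    * PREDICTION: all loci as reported (DYS389II stays the sum of both parts).
    * DISTANCE: all loci; the duplicated DYS385a/b pair is sorted ascending
      within each individual to remove the arbitrary a/b labelling.
    * NETWORK / RHO: DYS385a/b dropped; DYS389II replaced by
      DYS389II − DYS389I (the locus keeps the DYS389II name). Any arithmetic
      involving a missing allele yields missing.
    """
    _require_rounded(ds)
    panel = ds.panel
    if mode in (ViewMode.NETWORK, ViewMode.RHO):
        eff = [l for l in panel.loci if l not in panel.duplicated_loci]
    else:
        eff = list(panel.loci)
    composite = dict(panel.composite_pairs)  # part -> whole

    mat = np.full((len(ds.haplotypes), len(eff)), MISSING_INT, dtype=np.int64)
    for i, h in enumerate(ds.haplotypes):
        vals: dict[str, Optional[float]] = dict(h.alleles)
        if mode in (ViewMode.NETWORK, ViewMode.RHO):
            for part, whole in composite.items():
                p, w = vals.get(part), vals.get(whole)
                if p is MISSING or w is MISSING:
                    vals[whole] = MISSING
                else:
                    if w < p:
                        raise ValueError(
                            f"sample {h.sample_id}: {whole}={int(w)} < {part}={int(p)} "
                            "(impossible composite genotype)"
                        )
                    vals[whole] = w - p
        if mode is ViewMode.DISTANCE and len(panel.duplicated_loci) >= 2:
            # sort each duplicated pair (a,b) ascending within the individual
            for k in range(0, len(panel.duplicated_loci) - 1, 2):
                la, lb = panel.duplicated_loci[k], panel.duplicated_loci[k + 1]
                a, b = vals.get(la), vals.get(lb)
                if a is not MISSING and b is not MISSING and a > b:
                    vals[la], vals[lb] = b, a
        for j, loc in enumerate(eff):
            v = vals.get(loc)
            if v is not MISSING:
                mat[i, j] = int(v)
    return AnalysisView(
        source=ds,
        mode=mode,
        effective_loci=tuple(eff),
        matrix=mat,
        sample_ids=tuple(h.sample_id for h in ds.haplotypes),
        populations=tuple(h.population for h in ds.haplotypes),
        regions=tuple(h.region for h in ds.haplotypes),
    )


def write_arlequin_arp(
    ds: Dataset,
    path: str | Path,
    grouping: Optional[Mapping[str, str]] = None,
    missing_char: str = "?",
    title: str = "ystrpop export",
) -> None:
    """Write a haploid, microsatellite-type Arlequin project file.

    One sample block per population; each row is ``id  frequency  alleles...``.
    An optional structure section is emitted from ``grouping``
    (population → group name). Missing alleles are written as ``missing_char``.
    """
    _require_rounded(ds)
    path = Path(path)
    pops = ds.populations
    by_pop: dict[str, list[Haplotype]] = {p: [] for p in pops}
    for h in ds.haplotypes:
        by_pop[h.population].append(h)

    lines: list[str] = []
    lines += [
        "[Profile]",
        f'  Title="{title}"',
        f"  NbSamples={len(pops)}",
        "  GenotypicData=0",
        "  GameticPhase=0",
        "  DataType=MICROSAT",
        "  LocusSeparator=WHITESPACE",
        f"  MissingData='{missing_char}'",
        "",
        "[Data]",
        "  [[Samples]]",
    ]
    for pop in pops:
        members = by_pop[pop]
        lines.append(f'    SampleName="{pop}"')
        lines.append(f"    SampleSize={len(members)}")
        lines.append("    SampleData= {")
        for h in members:
            cells = []
            for loc in ds.panel.loci:
                a = h.alleles[loc]
                cells.append(missing_char if a is MISSING else str(int(a)))
            lines.append(f"      {h.sample_id} 1 " + " ".join(cells))
        lines.append("    }")
    if grouping:
        groups: dict[str, list[str]] = {}
        for pop in pops:
            groups.setdefault(grouping.get(pop, "ungrouped"), []).append(pop)
        lines += ["", "  [[Structure]]", '    StructureName="grouping"', f"    NbGroups={len(groups)}"]
        for gname, members in groups.items():
            lines.append("    Group= {")
            for pop in members:
                lines.append(f'      "{pop}"')
            lines.append("    }")
    path.write_text("\n".join(lines) + "\n")


def merge_datasets(a: Dataset, b: Dataset) -> Dataset:
    """Concatenate two datasets after intersecting to their shared loci.

    Loci present in only one dataset are dropped with a warning (e.g. merging
    a 27-locus with a 17-locus table keeps the 17 shared markers). Sample-id
    collisions are a hard error.
    """
    shared = [l for l in a.panel.loci if l in set(b.panel.loci)]
    dropped = (set(a.panel.loci) | set(b.panel.loci)) - set(shared)
    if dropped:
        warnings.warn(f"merge: dropping unshared loci {sorted(dropped)}")
    ids_a = {h.sample_id for h in a.haplotypes}
    collisions = ids_a & {h.sample_id for h in b.haplotypes}
    if collisions:
        raise ValueError(f"merge: sample_id collision(s): {sorted(collisions)}")
    panel = a.panel.restrict(shared) if dropped else a.panel
    keep = set(shared)
    haps = [
        replace(h, alleles={l: v for l, v in h.alleles.items() if l in keep})
        for h in a.haplotypes + b.haplotypes
    ]
    return Dataset(
        panel=panel,
        haplotypes=haps,
        provenance=f"merge({a.provenance!r}, {b.provenance!r})",
    )
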