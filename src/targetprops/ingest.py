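"""Parsing of UniProt-XML-like protein records and category dataset assembly.

The supported dialect is a documented subset of UniProt XML: ``entry``
elements carrying ``accession``, ``name``, ``sequence``, ``feature``,
``keyword`` and ``comment`` children (with or without the UniProt default
namespace).  Unknown elements are ignored, never fatal.

From parsed records plus supplemental accession lists the module assigns
protein-family flags (GPCR, ion channel, kinase, protease, cancer) and
builds the category datasets with positive/unlabelled labels: each
category has a membership criterion and a separate positive criterion,
with "unlabelled" rather than "negative" because future targets hide in
the non-positive class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from lxml import etree

from .constants import (
    KEYWORD_FAMILIES,
    KINASE_TYPES,
    N_BODY_SITES,
    N_DEV_STAGES,
    PROTEASE_TYPES,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "AnnotationBundle",
    "FamilyFlags",
    "SupplementalLists",
    "LabeledDataset",
    "UnionReport",
    "ParseError",
    "RecordError",
    "parse_uniprot_xml",
    "assign_families",
    "build_accession_map",
    "build_category_datasets",
    "union_target_sets",
    "read_accession_list",
    "read_annotation_table",
    "write_dataset_memberships",
]


class ParseError(ValueError):
    """Malformed XML input."""


class RecordError(ValueError):
    """A structurally valid entry missing required fields."""


@dataclass
class ProteinRecord:
    """One protein's accessions, sequence and parsed annotation counts."""

    representative_accession: str
    secondary_accessions: list[str] = field(default_factory=list)
    name: str = ""
    sequence: str = ""
    has_signal_peptide: bool = False
    n_glyc_sites: int = 0
    o_glyc_sites: int = 0
    phospho_ser: int = 0
    phospho_thr: int = 0
    phospho_tyr: int = 0
    tm_helices: int = 0
    binary_ppi_partners: set[str] = field(default_factory=set)
    keywords: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.representative_accession:
            raise RecordError("representative accession must be non-empty")
        if len(self.sequence) < 1:
            raise RecordError(
                f"record {self.representative_accession}: empty sequence"
            )


@dataclass
class AnnotationBundle:
    """External tool- and database-derived feature values for one protein."""

    accession: str
    pest_motifs: int = 0
    low_complexity_regions: int = 0
    frac_exposed_helix: float = 0.0
    frac_buried_helix: float = 0.0
    frac_beta_strand: float = 0.0
    var_3utr: int = 0
    var_5utr: int = 0
    var_nonsyn: int = 0
    var_syn: int = 0
    alt_transcripts: int = 0
    paralogues: int = 0
    expr_body_sites: tuple[float, ...] = (0.0,) * N_BODY_SITES
    expr_dev_stages: tuple[float, ...] = (0.0,) * N_DEV_STAGES

    def __post_init__(self) -> None:
        for name in ("frac_exposed_helix", "frac_buried_helix",
                     "frac_beta_strand"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if len(self.expr_body_sites) != N_BODY_SITES:
            raise ValueError(
                f"expr_body_sites must have length {N_BODY_SITES}"
            )
        if len(self.expr_dev_stages) != N_DEV_STAGES:
            raise ValueError(
                f"expr_dev_stages must have length {N_DEV_STAGES}"
            )


@dataclass
class FamilyFlags:
    """Protein-family membership flags for one record."""

    is_gpcr: bool = False
    is_ion_channel: bool = False
    is_kinase: bool = False
    is_protease: bool = False
    is_cancer: bool = False
    is_odorant_gpcr: bool = False
    kinase_type: str = "unknown"
    protease_type: str = "unknown"

    def __post_init__(self) -> None:
        if self.kinase_type not in KINASE_TYPES:
            raise ValueError(f"unknown kinase type {self.kinase_type!r}")
        if self.protease_type not in PROTEASE_TYPES:
            raise ValueError(f"unknown protease type {self.protease_type!r}")


@dataclass
class SupplementalLists:
    """Accession lists supplementing keyword-based family assignment."""

    gpcr_accessions: set[str] = field(default_factory=set)
    kinase_types: dict[str, str] = field(default_factory=dict)
    protease_types: dict[str, str] = field(default_factory=dict)
    cancer_gene_accessions: set[str] = field(default_factory=set)
    odorant_gpcr_accessions: set[str] = field(default_factory=set)


@dataclass
class LabeledDataset:
    """A named category dataset with positive/unlabelled labels."""

    name: str
    accessions: list[str]
    labels: dict[str, int]  # accession -> 1 (positive) / 0 (unlabelled)

    def __post_init__(self) -> None:
        missing = [a for a in self.accessions if a not in self.labels]
        if missing:
            raise ValueError(
                f"dataset {self.name}: labels missing for {missing[:5]}"
            )

    @property
    def n_positive(self) -> int:
        return sum(self.labels[a] for a in self.accessions)

    @property
    def n_unlabelled(self) -> int:
        return len(self.accessions) - self.n_positive

    @property
    def usable(self) -> bool:
        """Both classes present, as required before training."""
        return 0 < self.n_positive < len(self.accessions)

    def positives(self) -> list[str]:
        return [a for a in self.accessions if self.labels[a] == 1]


@dataclass
class UnionReport:
    union: set[str]
    a_only: int
    b_only: int
    both: int


def _localname(element) -> str:
    tag = element.tag
    return tag if not isinstance(tag, str) or "}" not in tag else tag.rsplit("}", 1)[1]


def _entry_children(entry, name: str):
    return [child for child in entry if _localname(child) == name]


def parse_uniprot_xml(
    xml_source,
    human_accessions: set[str] | None = None,
) -> list[ProteinRecord]:
    """Parse records from a stream/path of the supported UniProt-XML dialect.

    The first ``<accession>`` of each entry becomes the representative
    accession.  Glycosylation sites are split N/O by their description,
    phosphorylation sites S/T/Y by the "modified residue" description, and
    transmembrane helices counted when the feature type is "transmembrane
    region" with a description starting 'Helical'.  Binary interaction
    partners are unique partner accessions from two-interactant comments;
    when ``human_accessions`` is given, partners outside it are dropped.
    """
    try:
        tree = etree.parse(xml_source)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc
    root = tree.getroot()

    records = []
    for entry in root.iter():
        if _localname(entry) != "entry":
            continue
        accessions = [el.text.strip() for el in
                      _entry_children(entry, "accession") if el.text]
        names = [el.text.strip() for el in
                 _entry_children(entry, "name") if el.text]
        seq_elements = _entry_children(entry, "sequence")
        sequence = ""
        if seq_elements and seq_elements[0].text:
            sequence = "".join(seq_elements[0].text.split())
        entry_name = names[0] if names else (
            accessions[0] if accessions else "<unnamed>"
        )
        if not accessions:
            raise RecordError(f"entry {entry_name!r} has no accession")
        if not sequence:
            raise RecordError(f"entry {entry_name!r} has no sequence")

        record = ProteinRecord(
            representative_accession=accessions[0],
            secondary_accessions=accessions[1:],
            name=entry_name,
            sequence=sequence,
        )
        for kw in _entry_children(entry, "keyword"):
            kw_id = kw.get("id")
            if kw_id:
                record.keywords.add(kw_id)
        for feat in _entry_children(entry, "feature"):
            ftype = feat.get("type", "")
            desc = feat.get("description", "")
            if ftype == "signal peptide":
                record.has_signal_peptide = True
            elif ftype == "glycosylation site":
                if desc.startswith("N-linked"):
                    record.n_glyc_sites += 1
                elif desc.startswith("O-linked"):
                    record.o_glyc_sites += 1
            elif ftype == "modified residue":
                if desc.startswith("Phosphoserine"):
                    record.phospho_ser += 1
                elif desc.startswith("Phosphothreonine"):
                    record.phospho_thr += 1
                elif desc.startswith("Phosphotyrosine"):
                    record.phospho_tyr += 1
            elif ftype == "transmembrane region":
                if desc.startswith("Helical"):
                    record.tm_helices += 1
        own = set(accessions)
        for comment in _entry_children(entry, "comment"):
            if comment.get("type") != "interaction":
                continue
            ids = [el.text.strip()
                   for inter in comment
                   if _localname(inter) == "interactant"
                   for el in inter
                   if _localname(el) == "id" and el.text]
            if len(ids) < 2:
                continue  # unary interactions are not counted
            for partner in ids:
                if partner in own:
                    continue
                if human_accessions is not None and \
                        partner not in human_accessions:
                    continue
                record.binary_ppi_partners.add(partner)
        records.append(record)
    return records


def build_accession_map(records: Iterable[ProteinRecord]) -> dict[str, str]:
    """Map every (secondary or representative) accession to its representative."""
    mapping: dict[str, str] = {}
    for record in records:
        mapping[record.representative_accession] = \
            record.representative_accession
        for acc in record.secondary_accessions:
            mapping[acc] = record.representative_accession
    return mapping


def resolve_accessions(
    accessions: Iterable[str], accession_map: Mapping[str, str]
) -> set[str]:
    """Resolve accessions to representatives; unknown ones logged and skipped."""
    resolved = set()
    skipped = 0
    for acc in accessions:
        rep = accession_map.get(acc)
        if rep is None:
            skipped += 1
        else:
            resolved.add(rep)
    if skipped:
        logger.warning("%d accession(s) not resolvable; skipped", skipped)
    return resolved


def assign_families(
    record: ProteinRecord,
    keyword_map: Mapping[str, str] | None = None,
    supplemental: SupplementalLists | None = None,
) -> FamilyFlags:
    """Family flags for one record from keywords and supplemental lists.

    A flag is set if any keyword maps to the family or the accession is in
    the family's supplemental list; unknown keyword ids are ignored with a
    logged warning.  The cancer flag comes from the supplied cancer-gene
    accession set.
    """
    keyword_map = KEYWORD_FAMILIES if keyword_map is None else keyword_map
    supplemental = supplemental or SupplementalLists()
    flags = FamilyFlags()
    for kw in record.keywords:
        family = keyword_map.get(kw)
        if family is None:
            logger.warning("unknown keyword id %s ignored", kw)
            continue
        if family == "gpcr":
            flags.is_gpcr = True
        elif family == "ion_channel":
            flags.is_ion_channel = True
        elif family == "kinase":
            flags.is_kinase = True
        elif family == "protease":
            flags.is_protease = True
    acc = record.representative_accession
    if acc in supplemental.gpcr_accessions:
        flags.is_gpcr = True
    if acc in supplemental.kinase_types:
        flags.is_kinase = True
        flags.kinase_type = supplemental.kinase_types[acc]
    if acc in supplemental.protease_types:
        flags.is_protease = True
        flags.protease_type = supplemental.protease_types[acc]
    if acc in supplemental.cancer_gene_accessions:
        flags.is_cancer = True
    if acc in supplemental.odorant_gpcr_accessions:
        flags.is_odorant_gpcr = True
        flags.is_gpcr = True
    return flags


def union_target_sets(set_a: set[str], set_b: set[str]) -> UnionReport:
    """Union of two target-accession sets with an overlap report."""
    both = set_a & set_b
    return UnionReport(
        union=set_a | set_b,
        a_only=len(set_a) - len(both),
        b_only=len(set_b) - len(both),
        both=len(both),
    )


def build_category_datasets(
    records: Sequence[ProteinRecord],
    flags: Mapping[str, FamilyFlags],
    target_accessions: set[str],
    antineoplastic_target_accessions: set[str] | None = None,
) -> list[LabeledDataset]:
    """Build the category datasets plus the derived predicate-filter datasets.

    Base categories: AllTargets (everything; positive iff approved target),
    Cancer (cancer proteins; positive iff antineoplastic target),
    GPCR/IonChannel/Kinase/Protease (family members; positive iff target).
    Derived: GPCR_NO (non-odorant GPCRs), Kinase_TK/Kinase_NTK and
    Protease_MP/Protease_NMP (positives restricted to the subtype), and
    LargeFamilies/SmallFamilies (members of the four families vs the rest).

    Target accessions should be pre-resolved to representatives (see
    :func:`resolve_accessions`); cancer proteins are those flagged
    ``is_cancer`` or appearing in the antineoplastic target set.
    """
    antineoplastic = antineoplastic_target_accessions or set()
    accession_map = build_accession_map(records)
    targets = resolve_accessions(target_accessions, accession_map)
    antineoplastic = resolve_accessions(antineoplastic, accession_map)

    def dataset(name, member_pred, positive_pred) -> LabeledDataset:
        accs, labels = [], {}
        for record in records:
            acc = record.representative_accession
            flag = flags[acc]
            if not member_pred(acc, flag):
                continue
            accs.append(acc)
            labels[acc] = int(positive_pred(acc, flag))
        ds = LabeledDataset(name=name, accessions=accs, labels=labels)
        if not ds.usable:
            logger.warning(
                "dataset %s has a single class (%d positive of %d); "
                "unusable for training", name, ds.n_positive, len(accs),
            )
        return ds

    is_target = lambda acc, f: acc in targets
    in_family = lambda acc, f: (f.is_gpcr or f.is_ion_channel or
                                f.is_kinase or f.is_protease)

    datasets = [
        dataset("AllTargets", lambda a, f: True, is_target),
        dataset("Cancer",
                lambda a, f: f.is_cancer or a in antineoplastic,
                lambda a, f: a in antineoplastic),
        dataset("GPCR", lambda a, f: f.is_gpcr, is_target),
        dataset("IonChannel", lambda a, f: f.is_ion_channel, is_target),
        dataset("Kinase", lambda a, f: f.is_kinase, is_target),
        dataset("Protease", lambda a, f: f.is_protease, is_target),
        dataset("GPCR_NO",
                lambda a, f: f.is_gpcr and not f.is_odorant_gpcr, is_target),
        dataset("Kinase_TK", lambda a, f: f.is_kinase,
                lambda a, f: a in targets and f.kinase_type == "tyr"),
        dataset("Kinase_NTK", lambda a, f: f.is_kinase,
                lambda a, f: a in targets and f.kinase_type != "tyr"),
        dataset("Protease_MP", lambda a, f: f.is_protease,
                lambda a, f: a in targets and f.protease_type == "metallo"),
        dataset("Protease_NMP", lambda a, f: f.is_protease,
                lambda a, f: a in targets and f.protease_type != "metallo"),
        dataset("LargeFamilies", in_family, is_target),
        dataset("SmallFamilies",
                lambda a, f: not in_family(a, f), is_target),
    ]
    return datasets


def read_accession_list(path) -> set[str]:
    """Read an accession-list text file, one accession per line."""
    with open(path) as handle:
        return {line.strip() for line in handle if line.strip()}


def read_annotation_table(path) -> dict[str, AnnotationBundle]:
    """Read a TSV annotation table, one row per accession.

    Expected columns: accession, the scalar AnnotationBundle fields, and
    expression vectors as body_site_1..45 / dev_stage_1..7.
    """
    import pandas as pd

    frame = pd.read_csv(path, sep="\t")
    bundles = {}
    body_cols = [f"body_site_{i + 1}" for i in range(N_BODY_SITES)]
    dev_cols = [f"dev_stage_{i + 1}" for i in range(N_DEV_STAGES)]
    for _, row in frame.iterrows():
        acc = str(row["accession"])
        bundles[acc] = AnnotationBundle(
            accession=acc,
            pest_motifs=int(row.get("pest_motifs", 0)),
            low_complexity_regions=int(row.get("low_complexity_regions", 0)),
            frac_exposed_helix=float(row.get("frac_exposed_helix", 0.0)),
            frac_buried_helix=float(row.get("frac_buried_helix", 0.0)),
            frac_beta_strand=float(row.get("frac_beta_strand", 0.0)),
            var_3utr=int(row.get("var_3utr", 0)),
            var_5utr=int(row.get("var_5utr", 0)),
            var_nonsyn=int(row.get("var_nonsyn", 0)),
            var_syn=int(row.get("var_syn", 0)),
            alt_transcripts=int(row.get("alt_transcripts", 0)),
            paralogues=int(row.get("paralogues", 0)),
            expr_body_sites=tuple(float(row[c]) for c in body_cols)
            if all(c in frame.columns for c in body_cols)
            else (0.0,) * N_BODY_SITES,
            expr_dev_stages=tuple(float(row[c]) for c in dev_cols)
            if all(c in frame.columns for c in dev_cols)
            else (0.0,) * N_DEV_STAGES,
        )
    return bundles


def write_dataset_memberships(datasets: Sequence[LabeledDataset], path) -> None:
    """Write membership TSV: accession, dataset, label (positive/unlabelled)."""
    with open(path, "w") as handle:
        handle.write("accession\tdataset\tlabel\n")
        for ds in datasets:
            for acc in ds.accessions:
                label = "positive" if ds.labels[acc] else "unlabelled"
                handle.write(f"{acc}\t{ds.name}\t{label}\n")
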