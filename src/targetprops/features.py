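"""Sequence-derived protein features and assembly of the full feature table.

A protein is described by 104 numeric features spanning amino-acid
composition, simple sequence properties (length, hydrophobicity,
isoelectric point, signal peptide, PEST motifs, low-complexity regions),
post-translational modification counts, secondary structure, germline
variant counts, inter-protein relationships and expression levels.
Sequence-derived quantities are computed here; tool- and database-derived
annotations are carried in through :class:`targetprops.ingest.AnnotationBundle`.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import (
    AA_CATEGORIES,
    ACIDIC_RESIDUES,
    AMBIGUOUS_AA,
    BASIC_RESIDUES,
    BODY_SITE_FEATURES,
    DEV_STAGE_FEATURES,
    FEATURE_NAMES,
    KYTE_DOOLITTLE,
    N_BODY_SITES,
    PKA,
    STANDARD_AA,
    UNKNOWN_AA,
    VALID_AA,
)

logger = logging.getLogger(__name__)

__all__ = [
    "aa_counts",
    "aa_composition",
    "category_fractions",
    "mean_hydrophobicity",
    "isoelectric_point",
    "net_charge",
    "derived_expression_breadth",
    "assemble_feature_table",
    "write_feature_table",
    "read_feature_table",
]


class SequenceError(ValueError):
    """Raised for sequences containing characters outside the supported set."""


def _validate(sequence: str) -> str:
    if not sequence:
        raise SequenceError("sequence must have length >= 1")
    seq = sequence.upper()
    for pos, char in enumerate(seq):
        if char not in VALID_AA:
            raise SequenceError(
                f"invalid amino-acid code {char!r} at position {pos}"
            )
    return seq


def aa_counts(sequence: str) -> dict[str, float]:
    """Occurrence counts of the twenty standard amino acids.

    Ambiguous codes add 0.5 to each of their two possible residues
    (B -> D/N, J -> I/L, Z -> E/Q).  X counts toward sequence length only.
    """
    seq = _validate(sequence)
    counts = dict.fromkeys(STANDARD_AA, 0.0)
    for char in seq:
        if char in counts:
            counts[char] += 1.0
        elif char in AMBIGUOUS_AA:
            first, second = AMBIGUOUS_AA[char]
            counts[first] += 0.5
            counts[second] += 0.5
        # X: length only.
    return counts


def aa_composition(sequence: str) -> dict[str, float]:
    """Frequencies of the twenty standard amino acids (counts / length)."""
    counts = aa_counts(sequence)
    length = len(sequence)
    return {aa: count / length for aa, count in counts.items()}


def category_fractions(
    counts: Mapping[str, float], length: int
) -> dict[str, float]:
    """Fractions of residues in the eight amino-acid categories.

    ``counts`` are weighted occurrence counts from :func:`aa_counts`;
    each fraction is the summed member count divided by sequence length.
    """
    if length < 1:
        raise SequenceError("length must be >= 1")
    return {
        name: sum(counts[aa] for aa in members) / length
        for name, members in AA_CATEGORIES.items()
    }


def mean_hydrophobicity(sequence: str) -> float:
    """Mean Kyte-Doolittle hydropathy over the sequence.

    Ambiguous codes contribute the mean of their two residues' index
    values; X contributes 0 to the sum but counts toward length.
    """
    seq = _validate(sequence)
    total = 0.0
    for char in seq:
        if char in KYTE_DOOLITTLE:
            total += KYTE_DOOLITTLE[char]
        elif char in AMBIGUOUS_AA:
            first, second = AMBIGUOUS_AA[char]
            total += 0.5 * (KYTE_DOOLITTLE[first] + KYTE_DOOLITTLE[second])
    return total / len(seq)


def net_charge(sequence: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of the sequence at a given pH.

    One free N-terminus and one free C-terminus are assumed; side-chain
    contributions come from the ionizable residues (D, E, C, Y, H, K, R)
    with the pinned pKa table.  Ambiguous codes contribute half-counts of
    any ionizable member (B -> 0.5 D, Z -> 0.5 E).
    """
    counts = aa_counts(sequence)
    positive = 1.0 / (1.0 + 10.0 ** (ph - PKA["N_TERM"]))
    for res in BASIC_RESIDUES:
        positive += counts[res] / (1.0 + 10.0 ** (ph - PKA[res]))
    negative = 1.0 / (1.0 + 10.0 ** (PKA["C_TERM"] - ph))
    for res in ACIDIC_RESIDUES:
        negative += counts[res] / (1.0 + 10.0 ** (PKA[res] - ph))
    return positive - negative


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """pH at which the sequence's net charge is zero.

    Net charge is strictly decreasing in pH, so the root on [0, 14] is
    found by bisection to within ``tol``.
    """
    _validate(sequence)
    low, high = 0.0, 14.0
    while high - low > tol:
        mid = 0.5 * (low + high)
        if net_charge(sequence, mid) > 0.0:
            low = mid
        else:
            high = mid
    return 0.5 * (low + high)


def derived_expression_breadth(expr_body_sites: Sequence[float]) -> int:
    """Number of body sites with a strictly positive expression level."""
    values = np.asarray(expr_body_sites, dtype=float)
    if values.shape != (N_BODY_SITES,):
        raise ValueError(
            f"expected a {N_BODY_SITES}-vector, got shape {values.shape}"
        )
    return int(np.count_nonzero(values > 0))


def _sequence_features(sequence: str) -> dict[str, float]:
    counts = aa_counts(sequence)
    length = len(sequence)
    row: dict[str, float] = {
        f"freq_{aa}": counts[aa] / length for aa in STANDARD_AA
    }
    for name, value in category_fractions(counts, length).items():
        row[f"frac_{name}"] = value
    row["sequence_length"] = float(length)
    row["hydrophobicity"] = mean_hydrophobicity(sequence)
    row["isoelectric_point"] = isoelectric_point(sequence)
    return row


def assemble_feature_table(
    records: Iterable,
    bundles: Mapping[str, object],
) -> pd.DataFrame:
    """Assemble the canonical feature table, one row per protein record.

    ``records`` are :class:`targetprops.ingest.ProteinRecord`; ``bundles``
    maps representative accessions to
    :class:`targetprops.ingest.AnnotationBundle`.  Records without a
    bundle have all annotation-derived features imputed as zero (counted
    and logged).  Returns a DataFrame indexed by accession with the
    canonical feature columns.
    """
    rows = []
    index = []
    seen: set[str] = set()
    n_imputed = 0
    for record in records:
        acc = record.representative_accession
        if acc in seen:
            raise ValueError(f"duplicate accession {acc!r}")
        seen.add(acc)
        row = _sequence_features(record.sequence)
        row["signal_peptide"] = float(record.has_signal_peptide)
        row["n_glyc_sites"] = float(record.n_glyc_sites)
        row["o_glyc_sites"] = float(record.o_glyc_sites)
        row["phospho_ser"] = float(record.phospho_ser)
        row["phospho_thr"] = float(record.phospho_thr)
        row["phospho_tyr"] = float(record.phospho_tyr)
        row["phospho_total"] = float(
            record.phospho_ser + record.phospho_thr + record.phospho_tyr
        )
        row["tm_helices"] = float(record.tm_helices)
        row["binary_ppis"] = float(len(record.binary_ppi_partners))

        bundle = bundles.get(acc)
        if bundle is None:
            n_imputed += 1
            for name in (
                "pest_motifs", "low_complexity_regions",
                "frac_exposed_helix", "frac_buried_helix",
                "frac_beta_strand", "var_3utr", "var_5utr",
                "var_nonsyn", "var_syn", "alt_transcripts", "paralogues",
            ):
                row[name] = 0.0
            for name in DEV_STAGE_FEATURES + BODY_SITE_FEATURES:
                row[name] = 0.0
            row["body_sites_expressed"] = 0.0
        else:
            row["pest_motifs"] = float(bundle.pest_motifs)
            row["low_complexity_regions"] = float(
                bundle.low_complexity_regions
            )
            row["frac_exposed_helix"] = float(bundle.frac_exposed_helix)
            row["frac_buried_helix"] = float(bundle.frac_buried_helix)
            row["frac_beta_strand"] = float(bundle.frac_beta_strand)
            row["var_3utr"] = float(bundle.var_3utr)
            row["var_5utr"] = float(bundle.var_5utr)
            row["var_nonsyn"] = float(bundle.var_nonsyn)
            row["var_syn"] = float(bundle.var_syn)
            row["alt_transcripts"] = float(bundle.alt_transcripts)
            row["paralogues"] = float(bundle.paralogues)
            for name, value in zip(DEV_STAGE_FEATURES,
                                   bundle.expr_dev_stages):
                row[name] = float(value)
            for name, value in zip(BODY_SITE_FEATURES,
                                   bundle.expr_body_sites):
                row[name] = float(value)
            row["body_sites_expressed"] = float(
                derived_expression_breadth(bundle.expr_body_sites)
            )
        rows.append([row[name] for name in FEATURE_NAMES])
        index.append(acc)
    if n_imputed:
        logger.warning(
            "%d record(s) had no annotation bundle; "
            "annotation features imputed as 0", n_imputed,
        )
    return pd.DataFrame(rows, index=pd.Index(index, name="accession"),
                        columns=list(FEATURE_NAMES))


def write_feature_table(
    table: pd.DataFrame, path, labels: Sequence[int] | None = None
) -> None:
    """Write the feature table (plus optional 0/1 label column) as TSV."""
    out = table.copy()
    if labels is not None:
        out["label"] = np.asarray(labels, dtype=int)
    out.to_csv(path, sep="\t")


def read_feature_table(path) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Read a feature-table TSV; returns (table, labels-or-None)."""
    frame = pd.read_csv(path, sep="\t", index_col="accession")
    labels = None
    if "label" in frame.columns:
        labels = frame.pop("label").to_numpy(dtype=int)
    return frame, labels
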