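"""Seeded generators for feature tables, sequence families and XML fixtures.

These generators produce data with the statistical structure the analysis
assumes, so every pipeline stage is testable without external downloads:

* feature tables with per-feature effect sizes controlled on the
  probability-of-superiority (PS) scale — an informative feature is
  Normal(delta, 1) for positives and Normal(0, 1) for unlabelled with
  delta = sqrt(2) * Phi^-1(PS), for which PS has the closed form
  Phi(delta / sqrt(2));
* positive-unlabelled label contamination (a fraction of true positives
  hidden in the unlabelled class) and arbitrary class imbalance;
* sequence families with controlled within-family identity (per-site
  mutation from a shared root);
* UniProt-XML-dialect fixtures that round-trip exactly through
  :func:`targetprops.ingest.parse_uniprot_xml`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
from scipy.stats import norm, poisson
from scipy.optimize import brentq

from .constants import STANDARD_AA
from .ingest import ProteinRecord

__all__ = [
    "FeatureSpec",
    "SyntheticTableConfig",
    "SyntheticTable",
    "SequenceFamilyConfig",
    "gen_feature_table",
    "gen_sequences",
    "gen_uniprot_xml_fixture",
    "ps_to_shift",
    "poisson_rate_for_ps",
]


def ps_to_shift(target_ps: float) -> float:
    """Mean shift delta giving the target PS for unit-variance normals.

    For X ~ N(delta, 1) vs Y ~ N(0, 1), P(X > Y) = Phi(delta / sqrt(2)),
    so delta = sqrt(2) * Phi^-1(PS).
    """
    if not 0.0 < target_ps < 1.0:
        raise ValueError("target_PS must be in (0, 1)")
    return float(np.sqrt(2.0) * norm.ppf(target_ps))


def _poisson_ps(lam_pos: float, lam_unl: float) -> float:
    """PS between two Poisson variables (ties credited 0.5), truncated sum."""
    # Truncate far into both upper tails so the mass lost is negligible.
    tail = int(poisson.ppf(1 - 1e-12, max(lam_pos, lam_unl))) + 10
    k = np.arange(tail)
    pmf_pos = poisson.pmf(k, lam_pos)
    pmf_unl = poisson.pmf(k, lam_unl)
    cdf_unl = np.cumsum(pmf_unl)
    win = float(np.sum(pmf_pos[1:] * cdf_unl[:-1]))
    tie = float(np.sum(pmf_pos * pmf_unl))
    return win + 0.5 * tie


def poisson_rate_for_ps(target_ps: float, base_rate: float = 1.0) -> float:
    """Positive-class Poisson rate hitting the target PS against base_rate.

    Solved numerically (root finding on the truncated PS expression); the
    option for integer count features where a normal shift would be
    unrealistic.  Requires target_PS in (0.5, 1) — below 0.5, swap the
    roles of the classes.
    """
    if not 0.5 <= target_ps < 1.0:
        raise ValueError("target_PS must be in [0.5, 1)")
    if target_ps == 0.5:
        return base_rate
    return float(
        brentq(lambda lam: _poisson_ps(lam, base_rate) - target_ps,
               base_rate, base_rate * 500 + 500)
    )


@dataclass(frozen=True)
class FeatureSpec:
    """One informative feature: name, target PS and distribution family."""

    name: str
    target_ps: float
    family: str = "normal"  # "normal" | "poisson"

    def __post_init__(self) -> None:
        if not 0.0 < self.target_ps < 1.0:
            raise ValueError("target_PS must be in (0, 1)")
        if self.family not in ("normal", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class SyntheticTableConfig:
    n_pos: int
    n_unl: int
    features: Sequence[FeatureSpec] = ()
    n_noise_features: int = 0
    mislabel_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_unl < 1:
            raise ValueError("class counts must be >= 1")
        if not 0.0 <= self.mislabel_fraction < 1.0:
            raise ValueError("mislabel_fraction must be in [0, 1)")


@dataclass
class SyntheticTable:
    """Generated table with nominal PU labels and the hidden truth."""

    table: pd.DataFrame
    labels: np.ndarray       # nominal labels after contamination
    true_labels: np.ndarray  # generating-class labels

    @property
    def hidden_positives(self) -> np.ndarray:
        """Mask of true positives relabelled unlabelled."""
        return (self.true_labels == 1) & (self.labels == 0)


def gen_feature_table(config: SyntheticTableConfig) -> SyntheticTable:
    """Generate a PU feature table with controlled per-feature effect sizes.

    True positives come first in row order; after generation,
    ``mislabel_fraction`` of them (rounded down, chosen at random) are
    relabelled unlabelled.  Noise features are Normal(0, 1) in both
    classes.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_pos + config.n_unl
    true_labels = np.concatenate(
        [np.ones(config.n_pos, dtype=int), np.zeros(config.n_unl, dtype=int)]
    )
    columns: dict[str, np.ndarray] = {}
    for spec in config.features:
        if spec.family == "normal":
            delta = ps_to_shift(spec.target_ps)
            values = rng.standard_normal(n)
            values[true_labels == 1] += delta
        else:
            base_rate = 1.0
            if spec.target_ps >= 0.5:
                lam_pos = poisson_rate_for_ps(spec.target_ps, base_rate)
                lam_unl = base_rate
            else:
                lam_unl = poisson_rate_for_ps(1.0 - spec.target_ps,
                                              base_rate)
                lam_pos = base_rate
            values = np.where(
                true_labels == 1,
                rng.poisson(lam_pos, size=n),
                rng.poisson(lam_unl, size=n),
            ).astype(float)
        columns[spec.name] = values
    for i in range(config.n_noise_features):
        columns[f"noise_{i}"] = rng.standard_normal(n)
    table = pd.DataFrame(
        columns,
        index=pd.Index([f"SYN{i:05d}" for i in range(n)], name="accession"),
    )
    labels = true_labels.copy()
    n_hide = int(config.mislabel_fraction * config.n_pos)
    if n_hide:
        hide = rng.choice(config.n_pos, size=n_hide, replace=False)
        labels[hide] = 0
    return SyntheticTable(table=table, labels=labels,
                          true_labels=true_labels)


@dataclass
class SequenceFamilyConfig:
    n_families: int = 5
    members_per_family: int = 5
    root_length: int = 100
    mutation_probability: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_length < 10:
            raise ValueError("root_length must be >= 10")
        if not 0.0 <= self.mutation_probability <= 1.0:
            raise ValueError("mutation_probability must be in [0, 1]")


def gen_sequences(config: SequenceFamilyConfig) -> dict[str, str]:
    """Sequence families: a random root per family, members mutated per site.

    Each member substitutes every site independently with the configured
    probability (uniformly over the 20 standard amino acids, so a
    'mutation' keeps the residue with chance 1/20).  Within-family
    identity is high for small mutation probabilities; cross-family
    identity sits near the random baseline.  Ids are ``fam{i}_m{j}``.
    """
    rng = np.random.default_rng(config.seed)
    alphabet = np.array(list(STANDARD_AA))
    sequences: dict[str, str] = {}
    for fam in range(config.n_families):
        root = rng.integers(0, len(alphabet), size=config.root_length)
        for member in range(config.members_per_family):
            mutate = rng.random(config.root_length) \
                < config.mutation_probability
            seq = root.copy()
            if mutate.any():
                seq[mutate] = rng.integers(0, len(alphabet),
                                           size=int(mutate.sum()))
            sequences[f"fam{fam}_m{member}"] = "".join(alphabet[seq])
    return sequences


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for start in range(0, len(seq), 60):
                handle.write(seq[start:start + 60] + "\n")


def gen_uniprot_xml_fixture(records: Sequence[ProteinRecord]) -> str:
    """Emit the supported XML dialect such that parsing round-trips exactly.

    Counts become repeated ``feature`` elements; each binary interaction
    partner becomes a two-interactant ``comment``.
    """
    lines = ['<?xml version="1.0" encoding="UTF-8"?>', "<uniprot>"]
    for record in records:
        lines.append("  <entry>")
        for acc in [record.representative_accession,
                    *record.secondary_accessions]:
            lines.append(f"    <accession>{escape(acc)}</accession>")
        lines.append(f"    <name>{escape(record.name)}</name>")
        for kw in sorted(record.keywords):
            lines.append(f'    <keyword id="{escape(kw)}">keyword</keyword>')
        if record.has_signal_peptide:
            lines.append('    <feature type="signal peptide"/>')
        for _ in range(record.n_glyc_sites):
            lines.append('    <feature type="glycosylation site" '
                         'description="N-linked (GlcNAc...)"/>')
        for _ in range(record.o_glyc_sites):
            lines.append('    <feature type="glycosylation site" '
                         'description="O-linked (GalNAc...)"/>')
        for _ in range(record.phospho_ser):
            lines.append('    <feature type="modified residue" '
                         'description="Phosphoserine"/>')
        for _ in range(record.phospho_thr):
            lines.append('    <feature type="modified residue" '
                         'description="Phosphothreonine"/>')
        for _ in range(record.phospho_tyr):
            lines.append('    <feature type="modified residue" '
                         'description="Phosphotyrosine"/>')
        for _ in range(record.tm_helices):
            lines.append('    <feature type="transmembrane region" '
                         'description="Helical"/>')
        for partner in sorted(record.binary_ppi_partners):
            lines.append('    <comment type="interaction">')
            lines.append("      <interactant><id>"
                         f"{escape(record.representative_accession)}"
                         "</id></interactant>")
            lines.append(f"      <interactant><id>{escape(partner)}"
                         "</id></interactant>")
            lines.append("    </comment>")
        lines.append(f"    <sequence>{escape(record.sequence)}</sequence>")
        lines.append("  </entry>")
    lines.append("</uniprot>")
    return "\n".join(lines) + "\n"
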