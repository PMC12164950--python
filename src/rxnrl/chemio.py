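"""Molecule and reaction representation, SMILES canonicalization, tokenization, dataset I/O.

Reactions are stored in the serialized form ``p1.p2.....pn>>product`` where the
left-hand side merges reactants and reagents into a single precursor list and the
right-hand side is a single product species.  All species are canonicalized with
RDKit on construction, so string equality on serialized reactions is equivalence
of the underlying chemistry up to the canonical ordering.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

REACTION_ARROW = ">>"

#: Begin / end sentinels and padding used by the sequence models.
BOS, EOS, PAD, UNK = "<s>", "</s>", "<pad>", "<unk>"

# The standard SMILES token pattern used by molecular transformer models:
# bracket atoms, two-character elements (Cl, Br), ring-closure digits and
# the %nn two-digit ring closures are each a single token.
SMILES_TOKEN_PATTERN = re.compile(
    r"(\[[^\]]+\]|Br|Cl|Si|Se|se|@@|@|%\d{2}|[BCNOPSFIbcnops]|"
    r"[=#\-\+\\\/\(\)\.~:\*\$]|>>|\d)"
)


class InvalidMoleculeError(ValueError):
    """Raised when a SMILES string does not parse to a valid molecular graph."""


class ReactionFormatError(ValueError):
    """Raised when a reaction string is malformed (no arrow, empty side, ...)."""


class TokenizationError(ValueError):
    """Raised when a string contains characters outside the SMILES token grammar."""

    def __init__(self, offending: str, source: str):
        self.offending = offending
        self.source = source
        super().__init__(f"unknown characters {offending!r} in {source!r}")


def canonicalize_smiles(smiles: str) -> str:
    """Return the canonical SMILES of a molecule.

    Idempotent: ``canonicalize_smiles(canonicalize_smiles(s)) == canonicalize_smiles(s)``.

    Raises
    ------
    InvalidMoleculeError
        If the input is empty or does not parse.
    """
    if not smiles or not smiles.strip():
        raise InvalidMoleculeError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def is_valid_smiles(smiles: str) -> bool:
    """True if *smiles* parses to a valid (nonempty) molecule."""
    if not smiles or not smiles.strip():
        return False
    return Chem.MolFromSmiles(smiles) is not None


@dataclass(frozen=True)
class Molecule:
    """A molecule held as a SMILES string, canonical unless flagged otherwise."""

    smiles: str
    canonical: bool = True

    @classmethod
    def from_smiles(cls, smiles: str) -> "Molecule":
        return cls(canonicalize_smiles(smiles), canonical=True)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.smiles


@dataclass(frozen=True)
class Reaction:
    """A forward reaction: merged precursor list (reactants + reagents) and one product.

    ``product_aligned`` optionally carries an equivalent, non-canonical product
    SMILES whose atom ordering follows the substrate's — the serialization the
    sequence models are trained to emit.  Canonicalization is a global graph
    algorithm that small corpora cannot teach, so generation targets preserve
    the precursor frame while identity, comparison and storage stay canonical.
    """

    precursors: tuple[Molecule, ...]
    product: Molecule
    product_aligned: str | None = field(default=None, compare=False)

    @property
    def lhs(self) -> str:
        """Serialized left-hand side, ``p1.p2.....pn``."""
        return ".".join(m.smiles for m in self.precursors)

    @property
    def training_target(self) -> str:
        """Product serialization used as the decoder target."""
        return self.product_aligned or self.product.smiles

    def serialize(self) -> str:
        return f"{self.lhs}{REACTION_ARROW}{self.product.smiles}"

    def __str__(self) -> str:
        return self.serialize()


def parse_reaction(line: str) -> Reaction:
    """Parse ``lhs>>rhs`` into a :class:`Reaction` with all species canonicalized.

    The left-hand side is split on ``.`` into individual precursors.  The product
    must be a single species: dot-separated products are rejected.
    """
    if REACTION_ARROW not in line:
        raise ReactionFormatError(f"no reaction arrow in {line!r}")
    lhs, _, rhs = line.partition(REACTION_ARROW)
    lhs, rhs = lhs.strip(), rhs.strip()
    if not lhs:
        raise ReactionFormatError(f"empty precursor side in {line!r}")
    if not rhs:
        raise ReactionFormatError(f"empty product side in {line!r}")
    if "." in rhs:
        raise ReactionFormatError(f"multi-fragment product in {line!r}")
    precursors = tuple(Molecule.from_smiles(p) for p in lhs.split("."))
    product = Molecule.from_smiles(rhs)
    return Reaction(precursors=precursors, product=product)


def tokenize(text: str) -> list[str]:
    """Split a SMILES or serialized reaction string into vocabulary tokens.

    Multi-character elements (``Cl``, ``Br``), bracket atoms and the reaction
    arrow are single tokens; ring-closure digits are separate tokens.  The split
    is lossless: ``detokenize(tokenize(s)) == s``.
    """
    tokens = SMILES_TOKEN_PATTERN.findall(text)
    if "".join(tokens) != text:
        leftover = SMILES_TOKEN_PATTERN.sub("", text)
        raise TokenizationError(leftover, text)
    return tokens


def detokenize(tokens: Sequence[str]) -> str:
    """Inverse of :func:`tokenize`; sentinels and padding are dropped."""
    return "".join(t for t in tokens if t not in (BOS, EOS, PAD))


@dataclass
class DatasetReadReport:
    """Row-level accounting for :func:`read_dataset`."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped_missing: int = 0
    parse_errors: list[tuple[int, str]] = field(default_factory=list)


def read_dataset(path: str | Path, report: DatasetReadReport | None = None):
    """Read labeled reactions from a delimited text file.

    The file must have a header naming at least a ``reaction`` column; optional
    ``yield`` and ``label`` columns are picked up when present.  Rows with missing
    values in any present column are dropped and counted; rows whose reaction
    string fails to parse are collected in the report, never silently swallowed.

    Returns a list of :class:`rxnrl.datasets.LabeledReaction`.
    """
    from .datasets import LabeledReaction  # local import to avoid a cycle

    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"reaction": str, "label": str})
    if "reaction" not in df.columns:
        raise KeyError(f"missing required column 'reaction' in {path}")

    if report is None:
        report = DatasetReadReport()
    report.n_read = len(df)

    use_cols = [c for c in ("reaction", "yield", "label") if c in df.columns]
    mask_missing = df[use_cols].isna().any(axis=1)
    report.n_dropped_missing = int(mask_missing.sum())
    if report.n_dropped_missing:
        logger.info("dropped %d rows with missing values", report.n_dropped_missing)
    df = df[~mask_missing]

    records = []
    for idx, row in df.iterrows():
        try:
            rxn = parse_reaction(row["reaction"])
            aligned = row.get("product_aligned")
            if isinstance(aligned, str) and aligned:
                if canonicalize_smiles(aligned) != rxn.product.smiles:
                    raise InvalidMoleculeError(
                        f"aligned product {aligned!r} does not match {rxn.product.smiles!r}"
                    )
                rxn = dataclasses.replace(rxn, product_aligned=aligned)
            records.append(
                LabeledReaction(
                    reaction=rxn,
                    label=str(row["label"]) if "label" in use_cols else "positive",
                    yield_pct=float(row["yield"]) if "yield" in use_cols else None,
                )
            )
        except (InvalidMoleculeError, ReactionFormatError) as exc:
            report.parse_errors.append((int(idx), str(exc)))
    report.n_kept = len(records)
    if report.parse_errors:
        logger.warning("%d rows failed to parse", len(report.parse_errors))
    return records


def write_dataset(records: Iterable, path: str | Path) -> None:
    """Write labeled reactions to CSV/TSV (by extension); inverse of :func:`read_dataset`."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    rows = []
    for rec in records:
        row = {"reaction": rec.reaction.serialize(), "label": rec.label}
        if rec.yield_pct is not None:
            row["yield"] = rec.yield_pct
        if rec.reaction.product_aligned is not None:
            row["product_aligned"] = rec.reaction.product_aligned
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
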