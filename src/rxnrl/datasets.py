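"""Dataset construction: corpus cleaning, regio-negative generation, yield-threshold
labeling, and the scarce-positive / abundant-positive training regimes.

The central objects are :class:`LabeledReaction` (a reaction plus a positive/negative
outcome label and optional yield) and :class:`DatasetBundle` (train/valid/test splits
with positive:negative bookkeeping).  Negatives live only in the training split:
validation and test accuracy are measured on positive reactions, whose correct
product is unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .chemio import Molecule, Reaction, canonicalize_smiles

POSITIVE, NEGATIVE = "positive", "negative"

HALOGENS = frozenset((9, 17, 35, 53))  # F, Cl, Br, I


class NoMovableHalogenError(ValueError):
    """The product carries no halogen on an aromatic ring."""


class AmbiguousHalogenError(ValueError):
    """No aromatic halogen can be identified as the newly installed one."""


class MissingYieldError(ValueError):
    pass


class SplitRatioError(ValueError):
    pass


class EmptyPositivesError(ValueError):
    pass


@dataclass(frozen=True)
class LabeledReaction:
    """A reaction together with its experimental outcome.

    ``label`` is ``"positive"`` for a successful reaction and ``"negative"`` for a
    failed one (wrong regiochemistry, or yield at/below threshold).  ``yield_pct``
    is the observed yield in percent when known.
    """

    reaction: Reaction
    label: str = POSITIVE
    yield_pct: float | None = None

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE


@dataclass
class DatasetBundle:
    """Train/valid/test splits with positive:negative bookkeeping."""

    train: list[LabeledReaction]
    valid: list[LabeledReaction]
    test: list[LabeledReaction]
    seed: int = 0

    @property
    def train_positives(self) -> list[LabeledReaction]:
        return [r for r in self.train if r.is_positive]

    @property
    def train_negatives(self) -> list[LabeledReaction]:
        return [r for r in self.train if not r.is_positive]

    @property
    def pos_neg_ratio(self) -> float:
        """Train positives / train negatives (inf when there are no negatives)."""
        n_neg = len(self.train_negatives)
        return len(self.train_positives) / n_neg if n_neg else math.inf

    def validate(self) -> None:
        """Check that no reaction string appears in more than one split."""
        seen: dict[str, str] = {}
        for name, split in (("train", self.train), ("valid", self.valid), ("test", self.test)):
            for rec in split:
                key = rec.reaction.serialize()
                if key in seen and seen[key] != name:
                    raise ValueError(f"reaction {key} appears in both {seen[key]} and {name}")
                seen[key] = name

    def counts(self) -> dict[str, int]:
        return {
            "train_pos": len(self.train_positives),
            "train_neg": len(self.train_negatives),
            "valid_pos": sum(r.is_positive for r in self.valid),
            "test_pos": sum(r.is_positive for r in self.test),
        }


# ---------------------------------------------------------------------------
# corpus cleaning
# ---------------------------------------------------------------------------

def clean_corpus(
    records: Sequence[LabeledReaction],
    exclude_products: Iterable[str] = (),
) -> tuple[list[LabeledReaction], dict[str, int]]:
    """Apply the standard cleaning rules and report per-rule removal counts.

    Rules, in order: drop exact duplicate reaction strings; drop reactions whose
    product equals one of their own precursors (residual reactant on the product
    side); drop reactions whose product is in ``exclude_products`` (leakage guard
    against a fine-tuning set).  Species are canonical by construction, so no
    separate validity pass is needed here; unparsable rows are already rejected
    at parse time.

    Idempotent: cleaning a cleaned corpus removes nothing.
    """
    exclude = {canonicalize_smiles(s) for s in exclude_products}
    report = {"duplicates": 0, "residual_reactant": 0, "excluded_product": 0}
    seen: set[str] = set()
    kept: list[LabeledReaction] = []
    for rec in records:
        key = rec.reaction.serialize()
        if key in seen:
            report["duplicates"] += 1
            continue
        seen.add(key)
        product = rec.reaction.product.smiles
        if any(product == p.smiles for p in rec.reaction.precursors):
            report["residual_reactant"] += 1
            continue
        if product in exclude:
            report["excluded_product"] += 1
            continue
        kept.append(rec)
    return kept, report


# ---------------------------------------------------------------------------
# regio-negative generation
# ---------------------------------------------------------------------------

def _aromatic_halogen_indices(mol: Chem.Mol) -> list[int]:
    """Indices of halogen atoms bonded to an aromatic atom."""
    out = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() in HALOGENS and any(
            nb.GetIsAromatic() for nb in atom.GetNeighbors()
        ):
            out.append(atom.GetIdx())
    return out


def _delete_atom(mol: Chem.Mol, idx: int) -> Chem.Mol | None:
    em = Chem.RWMol(mol)
    em.RemoveAtom(idx)
    try:
        out = em.GetMol()
        Chem.SanitizeMol(out)
        return out
    except Exception:
        return None


def _attach_halogen(mol: Chem.Mol, site_idx: int, halogen_z: int) -> str | None:
    """Canonical SMILES of *mol* with a halogen added at aromatic carbon *site_idx*."""
    out = _attach_halogen_pair(mol, site_idx, halogen_z)
    return out[0] if out else None


def _attach_halogen_pair(
    mol: Chem.Mol, site_idx: int, halogen_z: int
) -> tuple[str, str] | None:
    """(canonical, substrate-aligned) SMILES of the halogenated molecule.

    The aligned form serializes the product in the substrate's atom order with
    the halogen appended, so a sequence model can produce it by copy-and-edit.
    """
    em = Chem.RWMol(mol)
    x = em.AddAtom(Chem.Atom(halogen_z))
    em.AddBond(site_idx, x, Chem.BondType.SINGLE)
    em.GetAtomWithIdx(site_idx).SetNoImplicit(False)
    em.GetAtomWithIdx(site_idx).SetNumExplicitHs(0)
    try:
        out = em.GetMol()
        Chem.SanitizeMol(out)
        return Chem.MolToSmiles(out), Chem.MolToSmiles(out, canonical=False)
    except Exception:
        return None


def aromatic_ch_sites(mol: Chem.Mol) -> list[int]:
    """Indices of aromatic carbons carrying at least one hydrogen."""
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIsAromatic() and a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1
    ]


def identify_moved_halogen(positive: Reaction) -> tuple[int, int]:
    """Find the newly installed halogen in a positive reaction's product.

    The moved halogen is the aromatic halogen that is present in the product but
    absent at that position in the precursors: deleting it must recover one of
    the precursor molecules.  Halogens retained from a precursor (e.g. an
    2-bromophenyl group carried through the reaction) never satisfy this test.

    Returns ``(atom_index_in_product, atomic_number)``.  When several
    symmetric-equivalent candidates qualify, the one with the lowest canonical
    rank is chosen, which makes the enumeration deterministic.
    """
    product = Chem.MolFromSmiles(positive.product.smiles)
    candidates = _aromatic_halogen_indices(product)
    if not candidates:
        raise NoMovableHalogenError(
            f"no aromatic halogen in product {positive.product.smiles}"
        )
    precursor_smiles = {p.smiles for p in positive.precursors}
    ranks = list(Chem.CanonicalRankAtoms(product))
    movable: list[tuple[int, int]] = []  # (canonical rank, atom idx)
    for idx in candidates:
        bare = _delete_atom(product, idx)
        if bare is not None and Chem.MolToSmiles(bare) in precursor_smiles:
            movable.append((ranks[idx], idx))
    if not movable:
        raise AmbiguousHalogenError(
            f"cannot identify the installed halogen in {positive.serialize()}"
        )
    movable.sort()
    idx = movable[0][1]
    return idx, product.GetAtomWithIdx(idx).GetAtomicNum()


def generate_regio_negatives(positive: Reaction) -> list[Reaction]:
    """Enumerate regio-isomeric negatives by moving the installed halogen.

    Every alternative aromatic C-H position of the substrate receives the
    halogen in turn; results are canonicalized, deduplicated, and the true
    product is excluded.  Each negative shares the positive's precursors, so
    the returned products are isomeric with the true product by construction.
    """
    product = Chem.MolFromSmiles(positive.product.smiles)
    halogen_idx, halogen_z = identify_moved_halogen(positive)
    bare = _delete_atom(product, halogen_idx)
    if bare is None:
        raise AmbiguousHalogenError(
            f"halogen deletion failed for {positive.product.smiles}"
        )
    true_product = positive.product.smiles
    negatives: list[Reaction] = []
    seen: set[str] = set()
    for site in aromatic_ch_sites(bare):
        pair = _attach_halogen_pair(bare, site, halogen_z)
        if pair is None or pair[0] == true_product or pair[0] in seen:
            continue
        smi, aligned = pair
        seen.add(smi)
        negatives.append(
            Reaction(
                precursors=positive.precursors,
                product=Molecule(smi),
                product_aligned=aligned,
            )
        )
    return negatives


# ---------------------------------------------------------------------------
# yield labeling and splits
# ---------------------------------------------------------------------------

def label_by_yield(record: LabeledReaction, threshold_pct: float = 1.0) -> LabeledReaction:
    """Relabel a reaction from its yield: positive iff ``yield_pct > threshold_pct``.

    The inequality is strict — a yield exactly at the threshold is negative.
    """
    if record.yield_pct is None:
        raise MissingYieldError(f"no yield recorded for {record.reaction.serialize()}")
    label = POSITIVE if record.yield_pct > threshold_pct else NEGATIVE
    return replace(record, label=label)


def largest_remainder_sizes(n: int, ratios: Sequence[float]) -> list[int]:
    """Integer split sizes summing to *n*, proportional to *ratios*.

    Largest-remainder rounding; ties go to the earlier split.
    """
    if any(r < 0 for r in ratios) or sum(ratios) <= 0:
        raise SplitRatioError(f"ratios must be nonnegative with positive sum: {ratios}")
    total = float(sum(ratios))
    exact = [n * r / total for r in ratios]
    sizes = [int(math.floor(e)) for e in exact]
    remainder = n - sum(sizes)
    order = sorted(range(len(ratios)), key=lambda i: (-(exact[i] - sizes[i]), i))
    for i in order[:remainder]:
        sizes[i] += 1
    return sizes


def split_dataset(
    records: Sequence[LabeledReaction],
    ratios: Sequence[float] = (0.4, 0.3, 0.3),
    seed: int = 0,
) -> DatasetBundle:
    """Randomly partition positives into train/valid/test; negatives go to train only.

    Positives are shuffled with the given seed and partitioned with sizes
    proportional to *ratios* (largest-remainder rounding), so the same seed
    always yields the same bundle.  Validation and test contain positives only:
    accuracy is measured on positive reactions, while negatives inform training.
    """
    if not records:
        raise ValueError("no records to split")
    positives = [r for r in records if r.is_positive]
    negatives = [r for r in records if not r.is_positive]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    shuffled = [positives[i] for i in order]
    n_train, n_valid, n_test = largest_remainder_sizes(len(positives), ratios)
    train = shuffled[:n_train] + negatives
    valid = shuffled[n_train : n_train + n_valid]
    test = shuffled[n_train + n_valid :]
    bundle = DatasetBundle(train=train, valid=valid, test=test, seed=seed)
    bundle.validate()
    return bundle


def subsample_positives(
    bundle: DatasetBundle, fraction: float = 0.1, seed: int = 0
) -> DatasetBundle:
    """Shrink the training positives to ``round(fraction * count)``, keeping all else.

    All training negatives and the validation/test splits are retained unchanged:
    this reproduces the scarce-positive regime in which the positive:negative
    ratio drops by the subsampling factor while the negative pool stays intact.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    positives = bundle.train_positives
    n_keep = int(round(fraction * len(positives)))
    if n_keep == 0:
        raise EmptyPositivesError(
            f"subsampling {len(positives)} positives at fraction {fraction} leaves none"
        )
    if n_keep == len(positives):
        return bundle
    rng = np.random.default_rng(seed)
    keep_idx = set(rng.choice(len(positives), size=n_keep, replace=False).tolist())
    kept = [r for i, r in enumerate(positives) if i in keep_idx]
    return DatasetBundle(
        train=kept + bundle.train_negatives,
        valid=bundle.valid,
        test=bundle.test,
        seed=seed,
    )
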