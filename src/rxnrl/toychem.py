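"""Synthetic desk-scale reaction corpus with known ground truth.

The generator emulates the statistical structure of a regioselectivity corpus:
a pool of substituted aromatic substrates undergoes electrophilic halogenation,
the single correct (positive) product places the halogen ortho to the directing
substituent, and every alternative aromatic C-H position yields an enumerable
regio-isomeric negative.  Because the rule is deterministic, evaluation carries
no label noise and the upper bound of discoverable positives is known exactly.

Three disjoint substrate partitions feed the pipeline: the regio family
(train/valid/test), a reward-tuning slice (classification data for the reward
encoder), and the pretraining corpus.  Pretraining mixes generic functional
group transforms with halogenations whose position only follows the ortho rule
half of the time, so the pretrained model speaks the SMILES language and places
halogens plausibly, but does not yet know the family's regiochemistry rule —
mirroring a patent-corpus-pretrained model meeting a specialised dataset.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chemio import Molecule, Reaction, canonicalize_smiles
from .datasets import (
    NEGATIVE,
    POSITIVE,
    DatasetBundle,
    LabeledReaction,
    aromatic_ch_sites,
    generate_regio_negatives,
    label_by_yield,
)


class InfeasibleSpecError(ValueError):
    """The scaffold pool cannot supply the requested number of distinct reactions."""


@dataclass
class ToySpec:
    """Size and seed of the synthetic corpus.

    ``n_positive`` is the number of positive reactions in the training split;
    ``target_neg_pos_ratio`` is the desired train negative:positive ratio,
    reached by drawing negatives from additional left-hand sides whose own
    positives are withheld (scarce-positive regimes keep the full negative
    pool of the underlying corpus).
    """

    n_scaffolds: int = 1500
    n_pretrain: int = 5000
    n_positive: int = 200
    target_neg_pos_ratio: float = 4.0
    seed: int = 0
    hte: bool = False
    max_heavy_atoms: int = 14  # caps substrate size, keeping sequences short

    def __post_init__(self):
        if min(self.n_scaffolds, self.n_pretrain, self.n_positive) <= 0:
            raise ValueError("all counts must be positive")
        if self.target_neg_pos_ratio < 1:
            raise ValueError("target_neg_pos_ratio must be >= 1")


# -- scaffold grammar -------------------------------------------------------

RING_TEMPLATES = [
    "c1ccccc1",      # benzene
    "c1ccncc1",      # pyridine
    "c1ccnnc1",      # pyridazine
    "c1cncnc1",      # pyrimidine
    "c1cnccn1",      # pyrazine
    "c1ccoc1",       # furan
    "c1ccsc1",       # thiophene
    "c1cc[nH]c1",    # pyrrole
    "Cn1cccc1",      # N-methylpyrrole
    "c1ocnc1",       # oxazole
    "c1scnc1",       # thiazole
    "c1conc1",       # isoxazole
    "c1csnc1",       # isothiazole
    "Cn1cccn1",      # N-methylpyrazole
    "Cn1ccnc1",      # N-methylimidazole
    "c1ccc2ccccc2c1",   # naphthalene
    "c1ccc2ncccc2c1",   # quinoline
    "c1ccc2cnccc2c1",   # isoquinoline
    "c1ccc2occc2c1",    # benzofuran
    "c1ccc2sccc2c1",    # benzothiophene
    "Cn1ccc2ccccc21",   # N-methylindole
    "c1ccc2nccnc2c1",   # quinoxaline
    "c1ccc2ocnc2c1",    # benzoxazole
]

#: Substituent fragments; the attachment point is atom 0 of the fragment.
SUBSTITUENTS = [
    "C", "CC", "CCC", "C(C)C", "CO", "CCO",
    "O", "OC", "OCC", "N", "NC", "N(C)C",
    "C#N", "CC#N", "C(C)=O", "C(N)=O", "C=O", "C(F)(F)F",
    "COC", "C=C", "CCCC", "OC(C)C", "C(=O)OC", "NCC",
    "CCC#N", "OCC(F)(F)F",
]

HALOGEN_REAGENTS = {"Br": "BrBr", "Cl": "ClCl"}


def _canonical_remap(mol: Chem.Mol, idx: int) -> tuple[str, Chem.Mol, int] | None:
    """Canonical SMILES, the reparsed molecule, and *idx* remapped into it.

    Parsing a canonical SMILES yields atoms in string order, which is what the
    aligned product serializations rely on.
    """
    smi = Chem.MolToSmiles(mol)
    if not mol.HasProp("_smilesAtomOutputOrder"):
        return None
    order = [int(t) for t in mol.GetProp("_smilesAtomOutputOrder").strip("[],").split(",")]
    m2 = Chem.MolFromSmiles(smi)
    if m2 is None or idx not in order:
        return None
    return smi, m2, order.index(idx)


def _attach_fragment(ring: Chem.Mol, site: int, fragment: str) -> Chem.Mol | None:
    frag = Chem.MolFromSmiles(fragment)
    if frag is None:
        return None
    combo = Chem.RWMol(Chem.CombineMols(ring, frag))
    combo.AddBond(site, ring.GetNumAtoms(), Chem.BondType.SINGLE)
    a = combo.GetAtomWithIdx(site)
    a.SetNoImplicit(False)
    a.SetNumExplicitHs(0)
    try:
        mol = combo.GetMol()
        Chem.SanitizeMol(mol)
        return mol
    except Exception:
        return None


@dataclass(frozen=True)
class Scaffold:
    """A substrate with its ground-truth halogenation outcome.

    Products are stored canonically; ``aligned_products`` holds the equivalent
    substrate-aligned serializations used as sequence-model targets.
    """

    substrate: str            # canonical SMILES
    halogen: str              # "Br" or "Cl"
    positive_product: str     # canonical SMILES, ortho rule
    all_products: tuple[str, ...]       # every distinct halogenation product
    aligned_products: tuple[str, ...] = ()  # parallel to all_products

    @property
    def lhs(self) -> str:
        return f"{self.substrate}.{HALOGEN_REAGENTS[self.halogen]}"

    def aligned_for(self, canonical_product: str) -> str | None:
        if canonical_product in self.all_products and self.aligned_products:
            return self.aligned_products[self.all_products.index(canonical_product)]
        return None

    def positive_reaction(self) -> Reaction:
        return Reaction(
            precursors=(Molecule(self.substrate), Molecule(HALOGEN_REAGENTS[self.halogen])),
            product=Molecule(self.positive_product),
            product_aligned=self.aligned_for(self.positive_product),
        )

    def negative_reactions(self) -> list[Reaction]:
        return generate_regio_negatives(self.positive_reaction())


def _halogenation_products(mol: Chem.Mol, attach_idx: int, halogen: str):
    """(ortho, all) halogenation products as (canonical, aligned) pairs."""
    from .datasets import _attach_halogen_pair  # shared primitive

    z = {"Br": 35, "Cl": 17}[halogen]
    ortho_sites = {
        nb.GetIdx()
        for nb in mol.GetAtomWithIdx(attach_idx).GetNeighbors()
        if nb.GetIsAromatic() and nb.GetAtomicNum() == 6 and nb.GetTotalNumHs() >= 1
    }
    ortho, all_prods, seen = [], [], set()
    for site in aromatic_ch_sites(mol):
        pair = _attach_halogen_pair(mol, site, z)
        if pair is None or pair[0] in seen:
            continue
        seen.add(pair[0])
        all_prods.append(pair)
        if site in ortho_sites:
            ortho.append(pair)
    return sorted(ortho), sorted(all_prods)


def build_scaffold_pool(spec: ToySpec) -> list[Scaffold]:
    """Enumerate, validate and shuffle the substrate pool.

    The directing rule: the halogen goes to an aromatic C-H position adjacent to
    the substituent's attachment carbon; when the two ortho positions give
    distinct products, the lexicographically smallest canonical SMILES is the
    designated positive — injective per scaffold by construction.  Scaffolds
    with fewer than two alternative positions (no informative negatives) are
    dropped.
    """
    rng = np.random.default_rng(spec.seed)
    scaffolds: list[Scaffold] = []
    seen_substrates: set[str] = set()
    halogen_names = sorted(HALOGEN_REAGENTS)
    for ring_smi in RING_TEMPLATES:
        ring = Chem.MolFromSmiles(ring_smi)
        if ring is None:
            continue
        site_classes: set[int] = set()
        ranks = list(Chem.CanonicalRankAtoms(ring, breakTies=False))
        for site in aromatic_ch_sites(ring):
            if ranks[site] in site_classes:
                continue
            site_classes.add(ranks[site])
            for sub in SUBSTITUENTS:
                mol = _attach_fragment(ring, site, sub)
                if mol is None or mol.GetNumHeavyAtoms() > spec.max_heavy_atoms:
                    continue
                remap = _canonical_remap(mol, site)
                if remap is None:
                    continue
                substrate, mol, site_c = remap
                if substrate in seen_substrates:
                    continue
                halogen = halogen_names[int(rng.integers(len(halogen_names)))]
                ortho, all_prods = _halogenation_products(mol, site_c, halogen)
                if not ortho or len(all_prods) < 3:
                    continue
                seen_substrates.add(substrate)
                scaffolds.append(
                    Scaffold(
                        substrate=substrate,
                        halogen=halogen,
                        positive_product=ortho[0][0],
                        all_products=tuple(c for c, _ in all_prods),
                        aligned_products=tuple(a for _, a in all_prods),
                    )
                )
    order = rng.permutation(len(scaffolds))
    pool = [scaffolds[i] for i in order][: spec.n_scaffolds]
    return pool


@dataclass
class PoolPartition:
    """Disjoint substrate slices feeding the pipeline stages."""

    family: list[Scaffold]
    reward_tune: list[Scaffold]
    pretrain: list[Scaffold]
    hte: list[Scaffold]


def partition_pool(
    spec: ToySpec,
    pool: list[Scaffold] | None = None,
    n_valid: int = 60,
    n_test: int = 60,
    n_reward_tune: int = 60,
    n_hte: int = 16,
) -> PoolPartition:
    """Carve the shuffled pool into family / reward-tune / pretrain / HTE slices."""
    pool = pool if pool is not None else build_scaffold_pool(spec)
    # family needs positives for train/valid/test plus negative-only donors
    avg_negs = max(
        1.0, float(np.mean([len(s.all_products) - 1 for s in pool])) if pool else 1.0
    )
    n_neg_needed = spec.target_neg_pos_ratio * spec.n_positive
    # 25% slack: the family slice's realized negatives-per-scaffold varies, and
    # the top-up in make_regio_family stops at the target anyway
    n_neg_only = max(0, math.ceil(1.25 * n_neg_needed / avg_negs) - spec.n_positive)
    n_family = spec.n_positive + n_valid + n_test + n_neg_only
    if n_family + n_reward_tune > len(pool):
        raise InfeasibleSpecError(
            f"pool of {len(pool)} scaffolds cannot supply {n_family} family + "
            f"{n_reward_tune} reward-tuning left-hand sides"
        )
    family = pool[:n_family]
    rest = pool[n_family:]
    reward_tune = rest[:n_reward_tune]
    rest = rest[n_reward_tune:]
    hte = rest[:n_hte] if spec.hte else []
    pretrain = rest[n_hte:] if spec.hte else rest
    return PoolPartition(family=family, reward_tune=reward_tune, pretrain=pretrain, hte=hte)


def scaffolds_to_records(scaffolds: list[Scaffold], with_negatives: bool = True) -> list[LabeledReaction]:
    records = []
    for sc in scaffolds:
        records.append(LabeledReaction(reaction=sc.positive_reaction(), label=POSITIVE))
        if with_negatives:
            records.extend(
                LabeledReaction(reaction=r, label=NEGATIVE) for r in sc.negative_reactions()
            )
    return records


def make_regio_family(
    spec: ToySpec,
    partition: PoolPartition | None = None,
    n_valid: int = 60,
    n_test: int = 60,
    split_seed: int | None = None,
) -> DatasetBundle:
    """Build the abundant-positive training regime from the scaffold pool.

    Training holds ``spec.n_positive`` positives with their negatives, topped up
    with negatives from additional left-hand sides (positives withheld) until
    the train negative:positive ratio reaches ``spec.target_neg_pos_ratio``
    within 20%.  Validation and test hold positives only.  Deterministic given
    the spec's seed; ``split_seed`` reshuffles which family scaffolds land in
    which split while the family membership itself stays fixed, giving the
    independent data splits used for multi-seed statistics.
    """
    partition = partition or partition_pool(spec, n_valid=n_valid, n_test=n_test)
    family = partition.family
    if split_seed is not None:
        order = np.random.default_rng(split_seed).permutation(len(family))
        family = [family[i] for i in order]
    n_total_pos = spec.n_positive + n_valid + n_test
    if len(family) < n_total_pos:
        raise InfeasibleSpecError(
            f"family slice has {len(family)} scaffolds, need {n_total_pos} positives"
        )
    valid_sc = family[:n_valid]
    test_sc = family[n_valid : n_valid + n_test]
    train_sc = family[n_valid + n_test : n_valid + n_test + spec.n_positive]
    donors = family[n_valid + n_test + spec.n_positive :]

    train = scaffolds_to_records(train_sc, with_negatives=True)
    target_neg = spec.target_neg_pos_ratio * spec.n_positive
    n_neg = sum(not r.is_positive for r in train)
    for sc in donors:
        if n_neg >= target_neg:
            break
        negs = [LabeledReaction(reaction=r, label=NEGATIVE) for r in sc.negative_reactions()]
        train.extend(negs)
        n_neg += len(negs)
    if n_neg < 0.8 * target_neg:
        raise InfeasibleSpecError(
            f"only {n_neg} negatives available, target {target_neg:.0f}"
        )
    bundle = DatasetBundle(
        train=train,
        valid=[LabeledReaction(reaction=sc.positive_reaction()) for sc in valid_sc],
        test=[LabeledReaction(reaction=sc.positive_reaction()) for sc in test_sc],
        seed=spec.seed if split_seed is None else split_seed,
    )
    bundle.validate()
    return bundle


def build_pretrain_extra_pool(
    spec: ToySpec,
    n_target: int,
    exclude_substrates: set[str],
    rng: np.random.Generator,
) -> list[Scaffold]:
    """Randomly sampled disubstituted scaffolds for pretraining.

    The disubstituted combinatorial space is far larger than the family's
    mono-substituted grammar, which gives the sequence model the substrate
    diversity it needs to learn to copy unseen ring skeletons.  Products are
    disjoint from the family's by construction (different substitution counts).
    """
    rings = [Chem.MolFromSmiles(r) for r in RING_TEMPLATES]
    rings = [r for r in rings if r is not None]
    # fused skeletons are the hardest to copy; oversample them threefold
    weights = np.array(
        [3.0 if r.GetRingInfo().NumRings() > 1 else 1.0 for r in rings]
    )
    weights /= weights.sum()
    halogen_names = sorted(HALOGEN_REAGENTS)
    out: list[Scaffold] = []
    seen: set[str] = set(exclude_substrates)
    attempts = 0
    while len(out) < n_target and attempts < 60 * n_target:
        attempts += 1
        ring = rings[int(rng.choice(len(rings), p=weights))]
        sites = aromatic_ch_sites(ring)
        if len(sites) < 2:
            continue
        i, j = rng.choice(len(sites), size=2, replace=False)
        s1, s2 = sites[int(i)], sites[int(j)]
        sub1 = SUBSTITUENTS[int(rng.integers(len(SUBSTITUENTS)))]
        sub2 = SUBSTITUENTS[int(rng.integers(len(SUBSTITUENTS)))]
        mol = _attach_fragment(ring, s1, sub1)
        if mol is None:
            continue
        mol = _attach_fragment(mol, s2, sub2)
        if mol is None or mol.GetNumHeavyAtoms() > spec.max_heavy_atoms:
            continue
        remap = _canonical_remap(mol, s1)
        if remap is None:
            continue
        substrate, mol, s1_c = remap
        if substrate in seen:
            continue
        halogen = halogen_names[int(rng.integers(len(halogen_names)))]
        ortho, all_prods = _halogenation_products(mol, s1_c, halogen)
        if len(all_prods) < 2:
            continue
        seen.add(substrate)
        out.append(
            Scaffold(
                substrate=substrate,
                halogen=halogen,
                positive_product=(ortho[0] if ortho else all_prods[0])[0],
                all_products=tuple(c for c, _ in all_prods),
                aligned_products=tuple(a for _, a in all_prods),
            )
        )
    return out


# -- pretraining corpus -----------------------------------------------------

def _loosen(atom: Chem.Atom) -> None:
    atom.SetNoImplicit(False)
    atom.SetNumExplicitHs(0)


def _edit_methylate(em: Chem.RWMol, match: tuple[int, ...]) -> None:
    c = em.AddAtom(Chem.Atom(6))
    em.AddBond(match[0], c, Chem.BondType.SINGLE)
    _loosen(em.GetAtomWithIdx(match[0]))


def _edit_acetylate(em: Chem.RWMol, match: tuple[int, ...]) -> None:
    c1 = em.AddAtom(Chem.Atom(6))
    c2 = em.AddAtom(Chem.Atom(6))
    o = em.AddAtom(Chem.Atom(8))
    em.AddBond(match[0], c1, Chem.BondType.SINGLE)
    em.AddBond(c1, c2, Chem.BondType.SINGLE)
    em.AddBond(c1, o, Chem.BondType.DOUBLE)
    _loosen(em.GetAtomWithIdx(match[0]))


def _edit_saturate(em: Chem.RWMol, match: tuple[int, ...]) -> None:
    bond = em.GetBondBetweenAtoms(match[0], match[1])
    bond.SetBondType(Chem.BondType.SINGLE)
    _loosen(em.GetAtomWithIdx(match[0]))
    _loosen(em.GetAtomWithIdx(match[1]))


_TRANSFORMS = [
    # (name, match SMARTS, reagent SMILES, graph edit); amide N is excluded
    # from acetylation (not nucleophilic enough)
    ("o_methylation", "[OX2H1]", "CI", _edit_methylate),
    ("n_acetylation", "[NX3;H2;!$(NC=O)]", "CC(=O)Cl", _edit_acetylate),
    ("nitrile_reduction", "[CX2]#[NX1]", "[H][H]", _edit_saturate),
    ("carbonyl_reduction", "[CX3;H1]=[OX1]", "[H][H]", _edit_saturate),
    ("alkene_reduction", "[CX3;H1]=[CX3;H2]", "[H][H]", _edit_saturate),
]

_TRANSFORM_PATTERNS = {smarts: Chem.MolFromSmarts(smarts) for _, smarts, _, _ in _TRANSFORMS}


def _apply_transform(substrate: str, smarts: str, reagent: str | None) -> Reaction | None:
    """Apply a functional-group edit, preserving the substrate's atom order.

    Editing in place (rather than via reaction templates, which renumber
    atoms) keeps the product's aligned serialization an in-frame edit of the
    substrate string.  Transforms apply only where the reactive site is
    unambiguous (exactly one match), so every recorded outcome is unique.
    """
    mol = Chem.MolFromSmiles(substrate)
    matches = mol.GetSubstructMatches(_TRANSFORM_PATTERNS[smarts])
    if len(matches) != 1:
        return None
    edit = next(fn for _, s, _, fn in _TRANSFORMS if s == smarts)
    em = Chem.RWMol(mol)
    edit(em, matches[0])
    try:
        out = em.GetMol()
        Chem.SanitizeMol(out)
        product = Chem.MolToSmiles(out)
        aligned = Chem.MolToSmiles(out, canonical=False)
    except Exception:
        return None
    precursors = [Molecule(substrate)]
    if reagent:
        precursors.append(Molecule(canonicalize_smiles(reagent)))
    return Reaction(
        precursors=tuple(precursors), product=Molecule(product), product_aligned=aligned
    )


@dataclass
class PretrainCorpus:
    """Pretraining reactions with a held-out slice for forgetting checks.

    The held-out slice contains only deterministic functional-group transforms:
    the mixed-rule halogenations are irreducibly ambiguous on unseen substrates
    and therefore cannot serve as a learnability or forgetting yardstick.
    """

    train: list[Reaction]
    test: list[Reaction]

    def __len__(self) -> int:
        return len(self.train) + len(self.test)

    @property
    def reactions(self) -> list[Reaction]:
        return self.train + self.test


def make_pretrain_corpus(
    spec: ToySpec,
    partition: PoolPartition | None = None,
    exclude_products: set[str] | None = None,
    test_fraction: float = 0.1,
) -> PretrainCorpus:
    """Generate ``spec.n_pretrain`` unique pretraining reactions.

    The corpus mixes generic functional-group transforms with halogenations
    whose position follows the family's ortho rule only half the time (the
    other half goes to a random alternative site), so pretraining teaches the
    reaction language without fixing the family's regiochemistry.  Products
    overlapping the regio family's validation/test products are excluded.
    """
    partition = partition or partition_pool(spec)
    if exclude_products is None:
        n_vt = 120  # default valid+test slice of the family partition
        exclude_products = {sc.positive_product for sc in partition.family[:n_vt]}
    rng = np.random.default_rng(spec.seed + 1)
    halogenations: list[Reaction] = []
    transforms: list[Reaction] = []
    seen: set[str] = set()

    def add(rxn: Reaction | None, sink: list[Reaction]) -> bool:
        if rxn is None:
            return False
        key = rxn.serialize()
        if key in seen or rxn.product.smiles in exclude_products:
            return False
        if any(rxn.product.smiles == p.smiles for p in rxn.precursors):
            return False
        seen.add(key)
        sink.append(rxn)
        return True

    # ~1.8 reactions per scaffold on average; top the mono-substituted leftovers
    # up with disubstituted scaffolds when the quota demands it
    pool = list(partition.pretrain)
    n_more = max(0, math.ceil(spec.n_pretrain / 1.4) - len(pool))
    if n_more:
        pool += build_pretrain_extra_pool(
            spec, n_more, {sc.substrate for sc in pool}, rng
        )
    for sc in pool:
        # mixed-rule halogenation: ortho half the time, a random other site otherwise
        products = list(sc.all_products)
        if rng.random() < 0.5 or len(products) == 1:
            product = sc.positive_product
        else:
            others = [p for p in products if p != sc.positive_product]
            product = others[int(rng.integers(len(others)))]
        add(
            Reaction(
                precursors=(
                    Molecule(sc.substrate),
                    Molecule(HALOGEN_REAGENTS[sc.halogen]),
                ),
                product=Molecule(product),
                product_aligned=sc.aligned_for(product),
            ),
            halogenations,
        )
        # at most one transform per reagent per substrate (priority = list
        # order), so every left-hand side has a unique recorded outcome
        used_reagents: set[str] = set()
        for _, smarts, reagent, _fn in _TRANSFORMS:
            if reagent in used_reagents:
                continue
            rxn = _apply_transform(sc.substrate, smarts, reagent)
            if rxn is not None and add(rxn, transforms):
                used_reagents.add(reagent)
        if len(halogenations) + len(transforms) >= spec.n_pretrain + 64:
            break
    n_total = len(halogenations) + len(transforms)
    if n_total < spec.n_pretrain:
        raise InfeasibleSpecError(
            f"pretraining pool exhausted at {n_total} < {spec.n_pretrain} reactions"
        )
    n_test = max(1, int(round(test_fraction * spec.n_pretrain)))
    if n_test > len(transforms):
        raise InfeasibleSpecError(
            f"only {len(transforms)} transform reactions for a test slice of {n_test}"
        )
    t_order = rng.permutation(len(transforms))
    test = [transforms[i] for i in t_order[:n_test]]
    train = [transforms[i] for i in t_order[n_test:]] + halogenations
    train = train[: spec.n_pretrain - n_test]
    order = rng.permutation(len(train))
    return PretrainCorpus(train=[train[i] for i in order], test=test)


# -- HTE-style screening grid ----------------------------------------------

#: (catalyst, solvent) condition pairs; catalysts are single-atom condition
#: tokens, solvents small molecules.
HTE_CONDITIONS = [
    ("[Pd]", "CCO"),
    ("[Pd]", "CS(C)=O"),
    ("[Cu]", "CCO"),
    ("[Cu]", "CS(C)=O"),
    ("[Ni]", "CCO"),
    ("[Ni]", "CS(C)=O"),
    ("[Fe]", "CCO"),
    ("[Fe]", "CS(C)=O"),
]


def _ring_size(substrate: str) -> int:
    mol = Chem.MolFromSmiles(substrate)
    ri = mol.GetRingInfo()
    return max((len(r) for r in ri.AtomRings()), default=0)


def _hte_success(sc: Scaffold, catalyst: str, solvent: str) -> bool:
    """Hidden deterministic yield rule of the screening grid.

    Pd converts six-membered substrates, Cu five-membered ones; Ni and Fe are
    inactive, and bulky substrates (12 heavy atoms or more) fail under every
    condition.  Substrates carrying O or N in the substituent additionally
    require the polar solvent (DMSO).
    """
    mol = Chem.MolFromSmiles(sc.substrate)
    if mol.GetNumHeavyAtoms() >= 12:
        return False
    size = _ring_size(sc.substrate)
    if catalyst == "[Pd]" and size != 6:
        return False
    if catalyst == "[Cu]" and size != 5:
        return False
    if catalyst in ("[Ni]", "[Fe]"):
        return False
    needs_polar = any(ch in sc.substrate for ch in ("O", "N"))
    if needs_polar and solvent != "CS(C)=O":
        return False
    return True


def make_hte_grid(
    spec: ToySpec,
    partition: PoolPartition | None = None,
    conditions: list[tuple[str, str]] | None = None,
    positive_fraction: float | None = None,
) -> list[LabeledReaction]:
    """Full factorial substrates x (catalyst, solvent) grid with rule-driven yields.

    Yields are deterministic given the spec's seed: successful combinations draw
    a yield in (10, 90]%, failures in (0, 1]%; labels then follow the strict
    >1% threshold.  ``positive_fraction`` overrides the structural rule with a
    random success rate, exposing the sparsity of competing positive/negative
    pairs as a knob.  Success probability is structurally non-uniform across
    substrates: some succeed under many conditions, others under none.
    """
    if not spec.hte:
        raise ValueError("spec.hte must be true for HTE grid generation")
    partition = partition or partition_pool(spec)
    conditions = conditions or HTE_CONDITIONS
    rng = np.random.default_rng(spec.seed + 2)
    records: list[LabeledReaction] = []
    for sc, (cat, solv) in itertools.product(partition.hte, conditions):
        if positive_fraction is None:
            success = _hte_success(sc, cat, solv)
        else:
            success = bool(rng.random() < positive_fraction)
        yield_pct = float(10 + 80 * rng.random()) if success else float(rng.random())
        rxn = Reaction(
            precursors=(
                Molecule(sc.substrate),
                Molecule(HALOGEN_REAGENTS[sc.halogen]),
                Molecule(canonicalize_smiles(cat)),
                Molecule(canonicalize_smiles(solv)),
            ),
            product=Molecule(sc.positive_product),
            product_aligned=sc.aligned_for(sc.positive_product),
        )
        rec = LabeledReaction(reaction=rxn, label=POSITIVE, yield_pct=yield_pct)
        records.append(label_by_yield(rec, threshold_pct=1.0))
    return records
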