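"""Prioritization funnel for historical substitutions along one branch.

Given marginal reconstructions of a parent and a child ancestor, the funnel
(1) lists every site where the two MAP states differ, (2) keeps the
confidently reconstructed ("true") substitutions plus ambiguous ones whose
alternative state cannot explain the difference away, (3) keeps sites
conserved across the whole dataset or within either functional lineage, and
(4) triages the survivors by structural context, dropping surface residues
with no assigned structural role.  Survivors are grouped into nested mutant
sets (active site; + tunnel/cofactor shells; all) for experimental testing.

Conservation is scored transparently as the modal-residue frequency (and
Shannon entropy) of each column over a clade subset of the alignment, with a
configurable conservation threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .asr import AncestralProfile, GapMask
from .formats import GAP, Alignment, CoordinateMap, ResidueAnnotation

logger = logging.getLogger(__name__)

PP_TRUE = 0.8  # MAP posterior above this at both nodes: a true substitution
PP_ALT = 0.2  # alternative-state posterior above this: state is plausible
CONSERVATION_THRESHOLD = 0.8  # modal-residue frequency for "conserved"

TRUE_SUBSTITUTION = "true_substitution"
AMBIGUOUS_INCLUDED = "ambiguous_included"
EXCLUDED = "excluded"

CONSERVED_ALL = "conserved_all"
CONSERVED_SN = "conserved_SN_lineage"
CONSERVED_BV = "conserved_BV_lineage"
NOT_CONSERVED = "not_conserved"


class FunnelError(ValueError):
    pass


@dataclass
class SubstitutionRecord:
    """One candidate historical substitution between two ancestors."""

    column: int  # 1-based alignment column
    position: int  # 1-based residue position in descendant numbering
    parent_state: str
    parent_pp: float
    parent_alt: str
    parent_alt_pp: float
    child_state: str
    child_pp: float
    child_alt: str
    child_alt_pp: float
    pp_class: str | None = None
    conservation: str | None = None
    category: str | None = None  # structural category
    location: str | None = None  # surface / core
    domain: str | None = None
    sets: set = field(default_factory=set)  # mutant-set memberships
    dropped_at: str | None = None  # funnel stage that removed the record

    @property
    def label(self) -> str:
        """Mutation-style label in descendant numbering, e.g. 'T60I'."""
        return f"{self.parent_state}{self.position}{self.child_state}"


@dataclass
class ConservationProfile:
    """Per-column conservation over one clade subset of the alignment."""

    clade: str
    modal_residue: np.ndarray  # '<U1'; '-' where a column is all-gap
    modal_frequency: np.ndarray  # in [0, 1]; 0 where all-gap
    entropy: np.ndarray  # bits, over non-gap residues
    conserved: np.ndarray  # bool at the configured threshold
    threshold: float


def enumerate_substitutions(
    parent_profile: AncestralProfile,
    child_profile: AncestralProfile,
    parent_mask: GapMask,
    child_mask: GapMask,
    coord_map: CoordinateMap,
) -> list[SubstitutionRecord]:
    """List every column, present in both ancestors, where the parent and
    child MAP states differ.  Positions are reported in descendant
    (child-ancestor) residue numbering via ``coord_map``."""
    if parent_profile.n_sites != child_profile.n_sites:
        raise FunnelError("parent and child profiles cover different site counts")
    if len(parent_mask.present) != parent_profile.n_sites or len(
        child_mask.present
    ) != child_profile.n_sites:
        raise FunnelError("gap mask length does not match profile length")
    records = []
    both_present = parent_mask.present & child_mask.present
    for col in np.flatnonzero(both_present) + 1:
        i = col - 1
        if parent_profile.map_state[i] == child_profile.map_state[i]:
            continue
        pos = coord_map.residue(int(col))
        if pos is None:
            raise FunnelError(
                f"column {col} present in both masks but not mapped to a "
                f"residue of {coord_map.seq_id!r}"
            )
        records.append(
            SubstitutionRecord(
                column=int(col),
                position=pos,
                parent_state=str(parent_profile.map_state[i]),
                parent_pp=float(parent_profile.pp_map[i]),
                parent_alt=str(parent_profile.alt_state[i]),
                parent_alt_pp=float(parent_profile.pp_alt[i]),
                child_state=str(child_profile.map_state[i]),
                child_pp=float(child_profile.pp_map[i]),
                child_alt=str(child_profile.alt_state[i]),
                child_alt_pp=float(child_profile.pp_alt[i]),
            )
        )
    logger.info(
        "%d substitutions on branch %s -> %s",
        len(records), parent_profile.node, child_profile.node,
    )
    return records


def classify_by_pp(
    record: SubstitutionRecord, pp_true: float = PP_TRUE, pp_alt: float = PP_ALT
) -> str:
    """Posterior-probability triage of one substitution.

    - ``true_substitution``: MAP posterior strictly above ``pp_true`` at both
      nodes.
    - ``ambiguous_included``: at every node reconstructed below ``pp_true``,
      the alternative state is itself plausible (posterior strictly above
      ``pp_alt``) and differs from the MAP state at the other node — so the
      substitution cannot be explained away as a reconstruction artifact.
    - ``excluded`` otherwise (including exact threshold equality, which is
      logged).
    """
    parent_ok = record.parent_pp > pp_true
    child_ok = record.child_pp > pp_true
    if parent_ok and child_ok:
        return TRUE_SUBSTITUTION
    weak = []
    if record.parent_pp < pp_true:
        weak.append((record.parent_alt, record.parent_alt_pp, record.child_state))
    if record.child_pp < pp_true:
        weak.append((record.child_alt, record.child_alt_pp, record.parent_state))
    if weak and all(
        alt_pp > pp_alt and alt != other_map for alt, alt_pp, other_map in weak
    ):
        return AMBIGUOUS_INCLUDED
    if not weak:  # one node exactly at the threshold
        logger.info("substitution %s at PP threshold; excluded", record.label)
    return EXCLUDED


def conservation_profile(
    alignment: Alignment,
    clade_ids: list[str],
    threshold: float = CONSERVATION_THRESHOLD,
    clade_name: str = "clade",
) -> ConservationProfile:
    """Modal-residue frequency and Shannon entropy per column over a clade
    subset.  Gaps are excluded from the counts; all-gap columns are labeled
    not conserved."""
    if not clade_ids:
        raise FunnelError("empty clade")
    sub = alignment.subset(list(clade_ids))
    S = sub.n_sites
    modal = np.full(S, GAP, dtype="<U1")
    modal_freq = np.zeros(S)
    entropy = np.zeros(S)
    for j in range(S):
        col = sub.matrix[:, j]
        residues = col[col != GAP]
        if residues.size == 0:
            continue
        states, counts = np.unique(residues, return_counts=True)
        freqs = counts / counts.sum()
        top = np.argmax(counts)
        modal[j] = states[top]
        modal_freq[j] = freqs[top]
        entropy[j] = -np.sum(freqs * np.log2(freqs))
    return ConservationProfile(
        clade=clade_name,
        modal_residue=modal,
        modal_frequency=modal_freq,
        entropy=entropy,
        conserved=modal_freq >= threshold,
        threshold=threshold,
    )


def label_conservation(
    record: SubstitutionRecord,
    profile_all: ConservationProfile,
    profile_sn: ConservationProfile,
    profile_bv: ConservationProfile,
) -> str:
    """Trichotomy used by the funnel: conserved across the whole dataset,
    conserved only within the heteroatom-oxidising (S/N) lineage, conserved
    only within the Baeyer-Villiger lineage, or not conserved."""
    j = record.column - 1
    if profile_all.conserved[j]:
        return CONSERVED_ALL
    if profile_sn.conserved[j]:
        return CONSERVED_SN
    if profile_bv.conserved[j]:
        return CONSERVED_BV
    return NOT_CONSERVED


@dataclass
class FunnelResult:
    records: list[SubstitutionRecord]  # every input record, labeled
    survivors: list[SubstitutionRecord]
    counts: dict


def apply_funnel(
    records: list[SubstitutionRecord],
    profile_all: ConservationProfile,
    profile_sn: ConservationProfile,
    profile_bv: ConservationProfile,
    annotations: dict[int, ResidueAnnotation],
    pp_true: float = PP_TRUE,
    pp_alt: float = PP_ALT,
) -> FunnelResult:
    """Run the three funnel stages, labeling every record and logging drops.

    Stage 1 keeps true and ambiguous-but-included substitutions; stage 2
    keeps records conserved across the dataset or in either lineage; stage 3
    attaches the structural annotation and drops surface residues of
    category 'other'.  Records missing an annotation survive unclassified
    with a warning.
    """
    counts = {"listed": len(records)}
    stage1 = []
    for rec in records:
        rec.pp_class = classify_by_pp(rec, pp_true=pp_true, pp_alt=pp_alt)
        if rec.pp_class in (TRUE_SUBSTITUTION, AMBIGUOUS_INCLUDED):
            stage1.append(rec)
        else:
            rec.dropped_at = "pp_filter"
            logger.info("dropped %s at pp_filter (%s)", rec.label, rec.pp_class)
    counts["pp_filtered"] = len(stage1)

    stage2 = []
    for rec in stage1:
        rec.conservation = label_conservation(rec, profile_all, profile_sn, profile_bv)
        if rec.conservation != NOT_CONSERVED:
            stage2.append(rec)
        else:
            rec.dropped_at = "conservation"
            logger.info("dropped %s at conservation", rec.label)
    counts["conserved"] = len(stage2)

    survivors = []
    for rec in stage2:
        ann = annotations.get(rec.position)
        if ann is None:
            logger.warning(
                "no structural annotation for residue %d (%s); kept unclassified",
                rec.position, rec.label,
            )
            survivors.append(rec)
            continue
        rec.category = ann.category
        rec.location = ann.location
        rec.domain = ann.domain
        if ann.location == "surface" and ann.category == "other":
            rec.dropped_at = "structure"
            logger.info("dropped %s at structure (surface/other)", rec.label)
        else:
            survivors.append(rec)
    counts["structural"] = len(survivors)
    return FunnelResult(records=list(records), survivors=survivors, counts=counts)


# categories pulled into the intermediate (12x-style) mutant set, beyond the
# active site
NEXT_PRIORITY_CATEGORIES = ("tunnel", "FAD_proximal", "NADPH_shell1")


def compose_mutant_sets(
    survivors: list[SubstitutionRecord],
    explicit: dict[str, list[int]] | None = None,
) -> dict[str, list[SubstitutionRecord]]:
    """Nested mutant sets from the funnel survivors.

    ``4x`` holds the active-site substitutions, ``12x`` adds the next
    structural priority group (tunnel, FAD-proximal, first NADPH shell), and
    ``16x`` holds every survivor; nesting 4x <= 12x <= 16x is asserted.
    ``explicit`` adds user-defined sets as residue-position lists; positions
    absent from the survivors raise an error naming them.
    """
    by_pos = {rec.position: rec for rec in survivors}
    core = [r for r in survivors if r.category == "active_site"]
    mid = core + [r for r in survivors if r.category in NEXT_PRIORITY_CATEGORIES]
    sets: dict[str, list[SubstitutionRecord]] = {
        "4x": core,
        "12x": mid,
        "16x": list(survivors),
    }
    assert {r.position for r in sets["4x"]} <= {r.position for r in sets["12x"]}
    assert {r.position for r in sets["12x"]} <= {r.position for r in sets["16x"]}
    for name, positions in (explicit or {}).items():
        missing = [p for p in positions if p not in by_pos]
        if missing:
            raise FunnelError(
                f"set {name!r} references positions absent from the "
                f"survivors: {missing}"
            )
        sets[name] = [by_pos[p] for p in positions]
    for name, members in sets.items():
        for rec in members:
            rec.sets.add(name)
    return sets
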