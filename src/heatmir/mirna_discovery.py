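"""Known-miRNA matching, novel hairpin screening, and base-bias statistics.

Known matching follows the sRNA-pipeline convention that an observed read
may differ from its database mature by length variation at either end plus
at most one internal substitution, encoded in a variant suffix appended to
the reference name (``_L-2R + 2``, ``_R + 1_1ss18TG``: end edits first, then
``<k>ss`` followed by 1-based position / reference base / observed base for
each substitution).

Novel candidates are screened with an eleven-criterion filter on the
precursor's predicted secondary structure: stem-bulge size, stem pair count,
hairpin and loop lengths, minimum free energy, and pairing quality of the
mature region within the stem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

_TO_DNA = str.maketrans("Uu", "Tt")


def _dna(seq: str) -> str:
    return seq.upper().translate(_TO_DNA)


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


# ---------------------------------------------------------------------------
# known-miRNA variant matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantDescriptor:
    """End edits and substitutions of an observed read vs a reference mature.

    ``left``/``right`` are signed edit sizes (positive = bases gained by the
    read, negative = reference bases trimmed).  Gained bases are recorded so
    the descriptor can regenerate the read.  Substitution positions are
    1-based in the observed read.
    """

    left: int = 0
    right: int = 0
    left_bases: str = ""
    right_bases: str = ""
    substitutions: tuple = ()  # of (position, ref_base, obs_base)

    @property
    def cost(self) -> int:
        return abs(self.left) + abs(self.right) + len(self.substitutions)

    def __str__(self) -> str:
        def fmt(n: int) -> str:
            return f" + {n}" if n > 0 else f"-{-n}"

        parts = ""
        if self.left:
            parts += f"L{fmt(self.left)}"
        if self.right:
            parts += f"R{fmt(self.right)}"
        if self.substitutions:
            ss = "".join(f"{pos}{ref}{obs}" for pos, ref, obs in self.substitutions)
            sub_part = f"{len(self.substitutions)}ss{ss}"
            parts = f"{parts}_{sub_part}" if parts else sub_part
        return parts

    def full_name(self, reference_name: str) -> str:
        suffix = str(self)
        return f"{reference_name}_{suffix}" if suffix else reference_name


def apply_variant(reference: str, descriptor: VariantDescriptor) -> str:
    """Reconstruct the observed read from reference + descriptor."""
    ref = _dna(reference)
    core = ref[max(0, -descriptor.left) : len(ref) - max(0, -descriptor.right)]
    read = list(_dna(descriptor.left_bases) + core + _dna(descriptor.right_bases))
    for pos, ref_base, obs_base in descriptor.substitutions:
        if read[pos - 1] != _dna(ref_base):
            raise ValueError(
                f"descriptor inconsistent: position {pos} holds {read[pos - 1]}, "
                f"expected {ref_base}"
            )
        read[pos - 1] = _dna(obs_base)
    return "".join(read)


@dataclass(frozen=True)
class KnownMatch:
    reference_name: str
    descriptor: VariantDescriptor

    @property
    def name(self) -> str:
        return self.descriptor.full_name(self.reference_name)


def _align_variant(read: str, ref: str, max_end: int, max_subs: int):
    """All (descriptor) alignments of read against ref within the edit bounds."""
    out = []
    delta = len(read) - len(ref)
    for left in range(-max_end, max_end + 1):
        right = delta - left
        if abs(right) > max_end:
            continue
        core_ref = ref[max(0, -left) : len(ref) - max(0, -right)]
        core_read = read[max(0, left) : len(read) - max(0, right)]
        if len(core_ref) != len(core_read) or not core_ref:
            continue
        subs = []
        offset = max(0, left)  # read position of the first core base
        for i, (a, b) in enumerate(zip(core_ref, core_read)):
            if a != b:
                subs.append((offset + i + 1, a, b))
        if len(subs) > max_subs:
            continue
        out.append(
            VariantDescriptor(
                left=left,
                right=right,
                left_bases=read[: max(0, left)],
                right_bases=read[len(read) - max(0, right) :] if right > 0 else "",
                substitutions=tuple(subs),
            )
        )
    return out


def match_known(
    read: str,
    known_db: dict[str, str],
    max_end_variation: int = 3,
    max_substitutions: int = 1,
) -> KnownMatch | None:
    """Best known-mature assignment of a read, or None.

    A read matches a reference if it equals the reference after trimming or
    extending at most ``max_end_variation`` nt at either end plus at most
    ``max_substitutions`` internal substitutions.  Among references the
    lowest total edit cost wins; ties break to the lexicographically
    smallest reference name (with a logged warning).
    """
    if not known_db:
        raise ValueError("known_db must be non-empty")
    read_dna = _dna(read)
    candidates = []
    for name in known_db:
        for desc in _align_variant(read_dna, _dna(known_db[name]), max_end_variation, max_substitutions):
            candidates.append((desc.cost, name, abs(desc.left), desc))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1], c[2], str(c[3])))
    best_cost = candidates[0][0]
    best_names = {name for cost, name, _, _ in candidates if cost == best_cost}
    if len(best_names) > 1:
        logger.warning(
            "read matches %d references equally well (%s); keeping %s",
            len(best_names), ", ".join(sorted(best_names)), candidates[0][1],
        )
    return KnownMatch(reference_name=candidates[0][1], descriptor=candidates[0][3])


# ---------------------------------------------------------------------------
# hairpin structure screening
# ---------------------------------------------------------------------------

@dataclass
class HairpinStructure:
    precursor_sequence: str
    dot_bracket: str
    mfe: float
    mature_start: int  # 1-based inclusive, within precursor
    mature_end: int
    arm: str = "5p"

    def __post_init__(self):
        if len(self.dot_bracket) != len(self.precursor_sequence):
            raise ValueError("dot-bracket and sequence lengths differ")
        if not 1 <= self.mature_start <= self.mature_end <= len(self.precursor_sequence):
            raise ValueError("mature region out of bounds")
        _pair_table(self.dot_bracket)  # raises on unbalanced brackets


def _pair_table(dot_bracket: str) -> dict[int, int]:
    """0-based partner map from a dot-bracket string."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, ch in enumerate(dot_bracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return pairs


def _unpaired_runs(n: int, pairs: dict[int, int]) -> list[tuple[int, int]]:
    """Maximal unpaired runs as (start, end) inclusive, 0-based."""
    runs = []
    i = 0
    while i < n:
        if i in pairs:
            i += 1
            continue
        j = i
        while j + 1 < n and j + 1 not in pairs:
            j += 1
        runs.append((i, j))
        i = j + 1
    return runs


def _terminal_loop(n: int, pairs: dict[int, int]) -> tuple[int, int] | None:
    """The principal hairpin loop: the largest unpaired run enclosed by an
    innermost pair (no paired position inside)."""
    best = None
    for i, j in pairs.items():
        if i > j:
            continue
        if any(k in pairs for k in range(i + 1, j)):
            continue
        run = (i + 1, j - 1)
        if run[1] < run[0]:
            continue
        if best is None or (run[1] - run[0]) > (best[1] - best[0]):
            best = run
    return best


@dataclass
class CriterionReport:
    table: pd.DataFrame = field(repr=False)

    @property
    def passed(self) -> bool:
        return bool(self.table["passed"].all())

    def failed_criteria(self) -> list[int]:
        return list(self.table.loc[~self.table["passed"], "criterion"])


#: criterion id -> (description, comparator, threshold)
HAIRPIN_CRITERIA = {
    1: ("max bulge size in stem (nt)", "le", 12),
    2: ("base pairs in stem", "ge", 16),
    3: ("hairpin length (nt)", "ge", 50),
    4: ("terminal loop length (nt)", "le", 200),
    5: ("minimum free energy (kcal/mol)", "le", -15.0),
    6: ("max bulge size in mature region (nt)", "le", 4),
    7: ("biased bulges in mature region", "le", 2),
    8: ("max biased-bulge size in mature region (nt)", "le", 2),
    9: ("paired bases in mature region", "ge", 12),
    10: ("errors (unpaired bases) in mature region", "le", 4),
    11: ("percent of mature region in stem", "ge", 80.0),
}


def _is_biased(run: tuple[int, int], pairs: dict[int, int], n: int) -> bool:
    """A bulge is biased (one-sided) when its flanking pairs are adjacent on
    the partner strand: all unpaired bases sit on this strand only."""
    a, b = run[0] - 1, run[1] + 1
    if a < 0 or b >= n or a not in pairs or b not in pairs:
        return False
    return abs(pairs[a] - pairs[b]) == 1


def hairpin_filter(h: HairpinStructure) -> CriterionReport:
    """Evaluate the eleven structural criteria on a candidate precursor."""
    n = len(h.precursor_sequence)
    pairs = _pair_table(h.dot_bracket)
    n_pairs = sum(1 for i, j in pairs.items() if i < j)
    loop = _terminal_loop(n, pairs)
    loop_positions = set(range(loop[0], loop[1] + 1)) if loop else set()
    loop_len = len(loop_positions)

    paired_positions = set(pairs)
    if paired_positions:
        outer_lo = min(paired_positions)
        outer_hi = max(paired_positions)
        stem_positions = {
            p for p in range(outer_lo, outer_hi + 1) if p not in loop_positions
        }
    else:
        stem_positions = set()

    runs = _unpaired_runs(n, pairs)
    # stem bulges: unpaired runs inside the paired span, excluding the loop
    stem_bulges = [
        r
        for r in runs
        if stem_positions and r[0] > min(stem_positions) and r[1] < max(stem_positions)
        and not loop_positions.issuperset(range(r[0], r[1] + 1))
    ]
    max_stem_bulge = max((r[1] - r[0] + 1 for r in stem_bulges), default=0)

    mature = set(range(h.mature_start - 1, h.mature_end))
    mature_len = len(mature)
    # bulges touching the mature region: full run length counts (a bulge
    # may extend past the region boundary); the terminal loop is a loop,
    # not a bulge
    mature_runs = [
        (r, r[1] - r[0] + 1)
        for r in runs
        if r != loop and mature.intersection(range(r[0], r[1] + 1))
    ]
    max_mature_bulge = max((size for _, size in mature_runs), default=0)
    biased = [(r, size) for r, size in mature_runs if _is_biased(r, pairs, n)]
    n_biased = len(biased)
    max_biased_size = max((size for _, size in biased), default=0)
    mature_paired = len(mature & paired_positions)
    mature_errors = mature_len - mature_paired
    pct_in_stem = 100.0 * len(mature & stem_positions) / mature_len

    values = {
        1: max_stem_bulge,
        2: n_pairs,
        3: n,
        4: loop_len if loop else n,  # structure with no loop is degenerate
        5: h.mfe,
        6: max_mature_bulge,
        7: n_biased,
        8: max_biased_size,
        9: mature_paired,
        10: mature_errors,
        11: pct_in_stem,
    }
    rows = []
    for cid, (desc, op, threshold) in HAIRPIN_CRITERIA.items():
        value = values[cid]
        ok = value <= threshold if op == "le" else value >= threshold
        rows.append(
            {"criterion": cid, "description": desc, "value": value,
             "threshold": threshold, "comparator": op, "passed": bool(ok)}
        )
    return CriterionReport(table=pd.DataFrame(rows))


def fold_sequence(seq: str):
    """Predict (dot_bracket, mfe) with the RNA folding engine, if installed.

    Folding is pluggable throughout the package: any caller may pass a
    precomputed structure instead.
    """
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "no folding engine available; supply a precomputed dot-bracket"
        ) from exc
    structure, mfe = RNA.fold(_rna(seq))
    return structure, float(mfe)


# ---------------------------------------------------------------------------
# provenance categories
# ---------------------------------------------------------------------------

CATEGORIES = ("gp1a", "gp1b", "gp2a", "gp2b", "gp3", "gp4")


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class CategoryEvidence:
    matched_mature_cotton: bool = False
    matched_precursor_cotton: bool = False
    matched_mature_other: bool = False
    genome_mappable: bool = True
    novel_hairpin_passed: bool = False


def classify_category(evidence: CategoryEvidence) -> str:
    """Provenance category of a miRNA from its database/genome evidence.

    gp1a/gp1b: cotton mature with/without a cotton precursor hit (gp1b
    locates the precursor on the genome); gp2a/gp2b: other-species mature
    with a cotton precursor hit / a precursor predicted from the genome;
    gp3: other-species hit not mappable to the genome; gp4: no database hit
    but a genome hairpin passing the structural filter.
    """
    ev = evidence
    if ev.matched_mature_cotton:
        if ev.matched_precursor_cotton:
            return "gp1a"
        if ev.genome_mappable:
            return "gp1b"
        raise ClassificationError("cotton mature without precursor or genome location")
    if ev.matched_mature_other:
        if ev.matched_precursor_cotton:
            return "gp2a"
        return "gp2b" if ev.genome_mappable else "gp3"
    if ev.novel_hairpin_passed:
        if not ev.genome_mappable:
            raise ClassificationError("novel hairpin must originate from the genome")
        return "gp4"
    raise ClassificationError("no database match and no passing hairpin")


# ---------------------------------------------------------------------------
# base-bias statistics
# ---------------------------------------------------------------------------

BASES = ("A", "C", "G", "U")


def _sequences(mirnas) -> list[str]:
    seqs = []
    for m in mirnas:
        seq = m if isinstance(m, str) else getattr(m, "mature_sequence")
        seqs.append(_rna(seq))
    if not seqs:
        raise ValueError("empty miRNA set")
    return seqs


def first_base_preference(mirnas) -> pd.DataFrame:
    """Per-length (18-25) proportion of each first base; rows sum to 1."""
    seqs = _sequences(mirnas)
    rows = {}
    for seq in seqs:
        length = len(seq)
        rows.setdefault(length, {b: 0 for b in BASES})
        if seq[0] in rows[length]:
            rows[length][seq[0]] += 1
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table = table.div(table.sum(axis=1), axis=0).rename_axis("length")
    return table[list(BASES)]


def positional_base_composition(mirnas) -> pd.DataFrame:
    """Per-position base proportions over miRNAs long enough to reach it."""
    seqs = _sequences(mirnas)
    max_len = max(len(s) for s in seqs)
    rows = {}
    for pos in range(1, max_len + 1):
        counts = {b: 0 for b in BASES}
        for seq in seqs:
            if len(seq) >= pos and seq[pos - 1] in counts:
                counts[seq[pos - 1]] += 1
        total = sum(counts.values())
        rows[pos] = {b: c / total for b, c in counts.items()} if total else counts
    table = pd.DataFrame.from_dict(rows, orient="index").rename_axis("position")
    return table[list(BASES)]


@dataclass
class MiRNARecord:
    name: str
    mature_sequence: str
    category: str
    precursor_id: str = ""
    chromosome: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    arm: str = "5p"

    @property
    def length(self) -> int:
        return len(self.mature_sequence)

    @property
    def first_base(self) -> str:
        return _rna(self.mature_sequence)[0]

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
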