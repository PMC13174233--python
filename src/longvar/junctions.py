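"""Breakpoint-junction analysis: microhomology, insertions and repair mechanism.

A rearrangement joins two reference breakpoints.  The sequence signature at
the junction points to the repair pathway that created it:

* a long (>= ~20 bp) stretch of homology between the joined flanks is the
  signature of non-allelic homologous recombination (NAHR);
* a short (2-20 bp) microhomology with no inserted bases indicates
  microhomology-mediated end joining (MMEJ) or a related replication-based
  mechanism (FoSTeS/MMBIR);
* a short insertion at the junction that is templated from sequence near
  either breakpoint indicates non-homologous end joining (NHEJ) with
  templated insertion, or template switching;
* a clean blunt join with neither signature indicates plain NHEJ.

Breakpoint context is given as the four reference flanks (up/downstream of
the left and right breakpoints); the junction sequence, when available from
reads spanning the join, is decomposed into a segment matching one flank,
an optional inserted stretch, and a segment matching the other flank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

MECHANISMS = (
    "NAHR-like",
    "MMEJ-like",
    "NHEJ-clean",
    "NHEJ-templated",
    "unclassified",
)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class BreakpointContext:
    """Reference flanks of the two breakpoints of one rearrangement.

    ``left_up``/``left_down`` flank the left breakpoint, ``right_up``/
    ``right_down`` the right one; all read 5'->3' on the reference strand.
    ``inverted`` marks joins where one side enters in inverted orientation.
    """

    svtype: str  # DEL | DUP | INV
    left_up: str
    left_down: str
    right_up: str
    right_down: str
    inverted: bool = False
    in_segdup: bool = False

    def __post_init__(self) -> None:
        for name in ("left_up", "left_down", "right_up", "right_down"):
            seq = getattr(self, name).upper()
            if not seq or set(seq) - set("ACGTN"):
                raise ValueError(f"{name} must be a nonempty ACGTN string")
            setattr(self, name, seq)

    def join_flanks(self) -> tuple[str, str]:
        """The two sequences meeting at the junction (donor, acceptor).

        Deletion joins left-upstream to right-downstream; a tandem
        duplication joins right-upstream back to left-downstream.  Inverted
        joins reverse-complement the re-entering side.
        """
        if self.svtype == "DEL":
            if self.inverted:
                return revcomp(self.right_down), self.left_down
            return self.left_up, self.right_down
        if self.svtype == "DUP":
            if self.inverted:
                return self.left_up, revcomp(self.right_up)
            return self.right_up, self.left_down
        if self.svtype == "INV":
            return self.left_up, revcomp(self.right_up)
        raise ValueError(f"unsupported svtype {self.svtype!r}")


@dataclass
class JunctionCall:
    microhomology_length: int
    microhomology_seq: str
    insertion: str
    templated: bool
    template_side: str | None
    mechanism: str
    low_confidence: bool = False


def microhomology(
    context: BreakpointContext, slack: int = 2
) -> tuple[int, str]:
    """Longest breakpoint-anchored homology shared by the joined flanks.

    For the join (X | Y) the search reports the longest k such that the
    first k bases of Y occur within the last k+slack bases of X, or the
    last k bases of X occur within the first k+slack bases of Y.  The small
    positional slack absorbs breakpoint placement ambiguity of a base or
    two; k = 0 means a blunt join.
    """
    x, y = context.join_flanks()
    best = (0, "")
    for k in range(1, min(len(x), len(y)) + 1):
        prefix = y[:k]
        if prefix in x[-(k + slack):]:
            best = (k, prefix)
            continue
        suffix = x[-k:]
        if suffix in y[: k + slack]:
            best = (k, suffix)
    return best


def align_junction(
    junction: str,
    context: BreakpointContext,
    match_score: int = 1,
    mismatch_score: int = -3,
    max_offset: int = 10,
    min_side: int = 15,
) -> dict:
    """Decompose a junction read sequence into flank matches + insertion.

    The junction is split at positions (a, b): the prefix ending at ``a`` is
    aligned end-anchored to the donor flank and the suffix starting at ``b``
    start-anchored to the acceptor flank, each allowing a small anchor
    offset (a consumed microhomology copy shifts the re-entry point) and
    scored +1/match, -3/mismatch so sporadic substitutions are absorbed but
    never extend a match.  The residual ``junction[a:b]`` is the inserted
    sequence.  Raises when either side matches fewer than ``min_side``
    bases.
    """
    junction = junction.upper()
    if len(junction) < 30:
        raise ValueError("junction sequence too short to align (<30 bp)")
    x, y = context.join_flanks()
    n = len(junction)

    def side_best(anchored_pairs) -> tuple[int, int]:
        best_score, best_len = 0, 0
        for flank_at in anchored_pairs:
            score = 0
            for length, (qc, fc) in enumerate(flank_at, start=1):
                score += match_score if qc == fc else mismatch_score
                if score > best_score:
                    best_score, best_len = score, length
        return best_score, best_len

    def left_best(a: int) -> tuple[int, int]:
        pairs = [
            [(junction[a - L], x[len(x) - off - L])
             for L in range(1, min(a, len(x) - off) + 1)]
            for off in range(max_offset + 1)
        ]
        return side_best(pairs)

    def right_best(b: int) -> tuple[int, int]:
        pairs = [
            [(junction[b + L - 1], y[off + L - 1])
             for L in range(1, min(n - b, len(y) - off) + 1)]
            for off in range(max_offset + 1)
        ]
        return side_best(pairs)

    lefts = [left_best(a) for a in range(n + 1)]
    rights = [right_best(b) for b in range(n + 1)]
    best_key, best_ab = None, None
    for a in range(n + 1):
        for b in range(a, n + 1):
            key = (lefts[a][0] + rights[b][0], -(b - a))
            if best_key is None or key > best_key:
                best_key, best_ab = key, (a, b)
    a, b = best_ab
    left_len, right_len = lefts[a][1], rights[b][1]
    if left_len < min_side or right_len < min_side:
        raise ValueError(
            f"unalignable junction: matched segments {left_len}/{right_len} bp "
            f"(need >= {min_side} each)"
        )
    return {
        "insertion": junction[a:b],
        "left_matched": left_len,
        "right_matched": right_len,
        "switch_point": a,
    }


def find_template(
    insertion: str, context: BreakpointContext, window: int = 100
) -> str | None:
    """Locate an inserted sequence near either breakpoint (both strands)."""
    if not insertion:
        return None
    sites = {
        "left": context.left_up[-window:] + context.left_down[:window],
        "right": context.right_up[-window:] + context.right_down[:window],
    }
    for side, seq in sites.items():
        if insertion in seq or revcomp(insertion) in seq:
            return side
    return None


def classify_mechanism(
    mh_length: int,
    insertion: str,
    templated: bool,
    in_segdup: bool = False,
    nahr_min: int = 20,
    mmej_range: tuple[int, int] = (2, 20),
    min_template_len: int = 4,
) -> str:
    """Mechanism label from the junction signature.

    NAHR-like for long homology (or breakpoints inside segmental
    duplications); MMEJ-like for short microhomology with no insertion;
    NHEJ-templated for an inserted stretch (>= 4 bp) copied from near a
    breakpoint; NHEJ-clean for a blunt join; otherwise unclassified.
    """
    if in_segdup or mh_length >= nahr_min:
        return "NAHR-like"
    if mmej_range[0] <= mh_length <= mmej_range[1] and not insertion:
        return "MMEJ-like"
    if len(insertion) >= min_template_len and templated:
        return "NHEJ-templated"
    if mh_length <= 1 and not insertion:
        return "NHEJ-clean"
    return "unclassified"


def classify_junction(
    context: BreakpointContext,
    junction: str | None = None,
    template_window: int = 100,
    mh_slack: int = 2,
    min_template_len: int = 4,
) -> JunctionCall:
    """Full junction call: microhomology, insertion, template, mechanism.

    Without a junction read sequence the insertion is taken as empty and
    classification rests on the flank homology alone.  Calls whose
    templated insertion is exactly the minimum length are flagged low
    confidence: a 4 bp match recurs by chance too easily to be definitive.
    """
    mh_len, mh_seq = microhomology(context, slack=mh_slack)
    insertion = ""
    if junction is not None:
        insertion = align_junction(junction, context)["insertion"]
    side = find_template(insertion, context, window=template_window)
    mechanism = classify_mechanism(
        mh_len,
        insertion,
        templated=side is not None,
        in_segdup=context.in_segdup,
        min_template_len=min_template_len,
    )
    return JunctionCall(
        microhomology_length=mh_len,
        microhomology_seq=mh_seq,
        insertion=insertion,
        templated=side is not None,
        template_side=side,
        mechanism=mechanism,
        low_confidence=(
            mechanism == "NHEJ-templated" and len(insertion) == min_template_len
        ),
    )
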