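"""Hairpin thermodynamics of editing: MFE folding, delta-delta-G, and the base
facing the edited position.

Folding is delegated to the ViennaRNA nearest-neighbor engine (Turner
parameters, 37 degrees C); this module owns everything around it: the
stability change upon editing

    ddG = dG(edited precursor) - dG(unedited precursor)   [kcal/mol]

(negative = the edit stabilizes the hairpin; ddG <= -6.0 kcal/mol is flagged
as strong stabilization, the regime where edited adenosines characteristically
sit opposite an unpaired cytosine that the I(G)-C pair then closes), and a
purely geometric classification of the base "facing" a position across the
stem of the minimum-free-energy structure.
"""

from __future__ import annotations

import dataclasses

from .refset import ReferenceSet

STRONG_STABILIZATION = -6.0  # kcal/mol
_TOL = 1e-6


def _engine():
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "RNA folding requires the ViennaRNA python bindings (import RNA)"
        ) from exc
    return RNA


def engine_version() -> str:
    return f"ViennaRNA {_engine().__version__}"


@dataclasses.dataclass(frozen=True)
class FoldResult:
    sequence: str
    structure: str   # dot-bracket
    delta_g: float   # MFE, kcal/mol at 37 C

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ValueError("structure length != sequence length")


def fold(sequence: str) -> FoldResult:
    """MFE structure and energy of an RNA sequence (Turner model, 37 C)."""
    sequence = sequence.upper().replace("T", "U")
    if len(sequence) < 10:
        raise ValueError("sequence shorter than 10 nt")
    if set(sequence) - set("ACGU"):
        raise ValueError("sequence must be over {A, C, G, U}")
    structure, energy = _engine().fold(sequence)
    return FoldResult(sequence, structure, round(float(energy), 2))


def pair_table(structure: str) -> list[int]:
    """1-based pairing partners (0 = unpaired); index 0 unused."""
    table = [0] * (len(structure) + 1)
    stack: list[int] = []
    for i, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            table[i], table[j] = j, i
        elif ch != ".":
            raise ValueError(f"illegal structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return table


def facing_base(result: FoldResult, position: int) -> str:
    """Classify what lies opposite ``position`` across the hairpin stem.

    Paired positions return ``paired:<partner base>``. For an unpaired
    position the innermost enclosing pair (i, j) is located and the opposite
    position interpolated as j - (position - i); this is only meaningful in a
    symmetric internal loop, so asymmetric loops, bulges, multiloop interiors
    and the terminal loop return ``bulge/ambiguous``.
    """
    table = pair_table(result.structure)
    n = len(result.sequence)
    if not 1 <= position <= n:
        raise ValueError(f"position {position} outside sequence")
    if table[position]:
        return f"paired:{result.sequence[table[position] - 1]}"

    # innermost enclosing pair: nearest paired position p <= position whose
    # partner lies beyond position
    i = j = 0
    depth_best = -1
    stack: list[int] = []
    for p, ch in enumerate(result.structure, start=1):
        if ch == "(":
            stack.append(p)
        elif ch == ")":
            q = stack.pop()
            if q < position < p and len(stack) + 1 > depth_best:
                depth_best = len(stack) + 1
                i, j = q, p
    if not i:
        return "bulge/ambiguous"  # not enclosed by any pair

    # children pairs of (i, j)
    children = []
    p = i + 1
    while p < j:
        if table[p] and table[p] > p:
            children.append((p, table[p]))
            p = table[p] + 1
        else:
            p += 1
    if len(children) != 1:
        return "bulge/ambiguous"  # terminal loop or multiloop interior
    p, q = children[0]
    side5 = p - i - 1
    side3 = j - q - 1
    if side5 != side3 or side5 == 0:
        return "bulge/ambiguous"  # bulge or asymmetric internal loop
    if i < position < p:
        f = j - (position - i)
    elif q < position < j:
        f = i + (j - position)
    else:  # pragma: no cover - enclosing-pair search guarantees containment
        return "bulge/ambiguous"
    if not i < f < j or table[f]:
        return "bulge/ambiguous"
    return f"mismatch:{result.sequence[f - 1]}"


@dataclasses.dataclass(frozen=True)
class EditStabilityResult:
    precursor_id: str
    position: int
    edit_type: str
    dg_unedited: float
    dg_edited: float
    ddg: float
    category: str            # stabilized / unchanged / destabilized
    strong_flag: bool        # ddg <= -6.0 kcal/mol
    facing: str              # classification on the UNEDITED structure
    facing_edited: str       # secondary: same classification after editing
    structure_unedited: str
    structure_edited: str
    engine: str


def _categorize(ddg: float) -> str:
    if abs(ddg) < _TOL:
        return "unchanged"
    return "stabilized" if ddg < 0 else "destabilized"


def delta_delta_g(
    refset: ReferenceSet,
    precursor_id: str,
    position: int,
    edit_type: str,
) -> EditStabilityResult:
    """Fold the unedited and edited precursor and report the stability change.

    ``edit_type`` is "A>G" or "C>U" (or any "X>Y" substitution; X must match
    the reference base). The facing classification is computed on the unedited
    structure — the substrate the editing enzyme actually sees.
    """
    ref_base, alt_base = edit_type[0], edit_type[-1]
    rec = refset[precursor_id]
    if rec.base(position) != ref_base:
        raise ValueError(
            f"{precursor_id}:{position} is {rec.base(position)}, "
            f"not {ref_base} as required by {edit_type}"
        )
    unedited = fold(rec.sequence)
    edited_seq = rec.sequence[: position - 1] + alt_base + rec.sequence[position:]
    if edited_seq == rec.sequence:  # identity edit
        edited = unedited
    else:
        edited = fold(edited_seq)
    ddg = round(edited.delta_g - unedited.delta_g, 2)
    return EditStabilityResult(
        precursor_id=precursor_id,
        position=position,
        edit_type=edit_type,
        dg_unedited=unedited.delta_g,
        dg_edited=edited.delta_g,
        ddg=ddg,
        category=_categorize(ddg),
        strong_flag=ddg <= STRONG_STABILIZATION,
        facing=facing_base(unedited, position),
        facing_edited=facing_base(edited, position),
        structure_unedited=unedited.structure,
        structure_edited=edited.structure,
        engine=engine_version(),
    )


def stability_table(results: list[EditStabilityResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "precursor": r.precursor_id,
                "position": r.position,
                "type": r.edit_type,
                "dG_unedited": r.dg_unedited,
                "dG_edited": r.dg_edited,
                "ddG": r.ddg,
                "category": r.category,
                "strong": r.strong_flag,
                "facing": r.facing,
                "engine": r.engine,
            }
            for r in results
        ]
    )
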