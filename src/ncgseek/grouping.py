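"""Non-collision grouping (NCG) of 16-bit data fragments.

Distinct fragments are packed into groups such that no two members of a
group share a 1-bit at the same position ("non-collision").  One column of
the reference matrix then encodes a whole group: each member's 1-bits are
marked with that member's pointer base, everything else with the group's
filler base.  Up to three members fit per group -- four pointers would leave
no base for the filler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_CAPACITY = 3
INDEX_DIGITS = 6
INDEX_RADIX = 3


def encoding_volume(index_digits: int = INDEX_DIGITS, radix: int = INDEX_RADIX) -> int:
    """Number of addressable groups: radix**index_digits (729 by default)."""
    if index_digits < 1 or radix < 2:
        raise ValueError("index_digits must be >= 1 and radix >= 2")
    return radix ** index_digits


MAX_GROUPS = encoding_volume()


@dataclass
class BaseMappingMatrix:
    """Cyclic base order used to hand out pointer and filler bases.

    Member of rank ``r`` in group ``g`` gets pointer ``order[(g + r) % 4]``;
    the filler is the next base in the cycle after the pointers.  This
    traversal produces reference-pool columns that cycle through 'ACGT' and
    its shifted permutations.
    """

    order: str = "ACGT"

    def __post_init__(self) -> None:
        if sorted(self.order) != list("ACGT"):
            raise ValueError("order must be a permutation of ACGT")

    def pointer(self, group_index: int, rank: int) -> str:
        return self.order[(group_index + rank) % 4]

    def filler(self, group_index: int, n_members: int) -> str:
        return self.order[(group_index + n_members) % 4]


@dataclass
class Group:
    index: int
    members: list[int] = field(default_factory=list)
    pointers: list[str] = field(default_factory=list)
    filler: str = ""

    def collides(self, fragment: int) -> bool:
        return any(fragment & m for m in self.members)


@dataclass
class GroupTable:
    groups: list[Group]
    dictionary: dict[int, tuple[int, str]] = field(default_factory=dict)
    matrix: BaseMappingMatrix = field(default_factory=BaseMappingMatrix)

    def __len__(self) -> int:
        return len(self.groups)

    def lookup(self, fragment: int) -> tuple[int, str]:
        try:
            return self.dictionary[fragment]
        except KeyError:
            raise KeyError(
                f"fragment 0x{fragment:04X} absent from dictionary"
            ) from None

    def fragment_at(self, group_index: int, pointer: str) -> int | None:
        """Inverse lookup; None if (group, pointer) addresses no member."""
        group = self.groups[group_index]
        for m, p in zip(group.members, group.pointers):
            if p == pointer:
                return m
        return None


def build_groups(
    fragments: list[int],
    capacity: int = DEFAULT_CAPACITY,
    max_groups: int = MAX_GROUPS,
) -> GroupTable:
    """Greedy first-fit packing of distinct fragments, first-occurrence order.

    Each new distinct fragment joins the lowest-index group where it collides
    with no member and capacity is free, else opens a new group.  Raises if
    more than ``max_groups`` groups would be needed (a second dictionary /
    reference pool would be required).
    """
    if not 1 <= capacity <= 3:
        raise ValueError("capacity must be between 1 and 3")
    groups: list[Group] = []
    seen: set[int] = set()
    for frag in fragments:
        if not 0 < frag < 1 << 16:
            raise ValueError(f"fragment out of 16-bit range: {frag}")
        if frag in seen:
            continue
        seen.add(frag)
        for group in groups:
            if len(group.members) < capacity and not group.collides(frag):
                group.members.append(frag)
                break
        else:
            if len(groups) >= max_groups:
                raise ValueError(
                    f"more than {max_groups} groups required; the corpus needs "
                    "a second dictionary/reference pool"
                )
            groups.append(Group(index=len(groups), members=[frag]))
    return GroupTable(groups=groups)


def assign_pointers(table: GroupTable, matrix: BaseMappingMatrix | None = None) -> GroupTable:
    """Assign pointer and filler bases by cyclic traversal of the base order."""
    if matrix is not None:
        table.matrix = matrix
    table.dictionary = {}
    for group in table.groups:
        group.pointers = [
            table.matrix.pointer(group.index, r) for r in range(len(group.members))
        ]
        group.filler = table.matrix.filler(group.index, len(group.members))
        for member, pointer in zip(group.members, group.pointers):
            table.dictionary[member] = (group.index, pointer)
    return table


def build_group_table(fragments: list[int], capacity: int = DEFAULT_CAPACITY,
                      matrix: BaseMappingMatrix | None = None) -> GroupTable:
    """Convenience: pack fragments and assign pointers in one step."""
    return assign_pointers(build_groups(fragments, capacity), matrix)


def multi_member_count(table: GroupTable) -> int:
    return sum(1 for g in table.groups if len(g.members) >= 2)
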