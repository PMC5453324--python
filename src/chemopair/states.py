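"""Allele-specific copy-number state conventions.

A state is a pair ``(n_a, n_b)`` of nonnegative integer copy counts for the
two parental alleles with ``n_a >= n_b`` by convention when unanchored.
String form follows the ASCAT convention: ``"AAB"`` means two copies of
allele A and one of allele B; ``"AA"`` is copy-neutral LOH ``(2, 0)``.
"""

from __future__ import annotations

State = tuple[int, int]


def state_to_string(state: State) -> str:
    """Render ``(n_a, n_b)`` as an allele string, e.g. ``(2, 1) -> "AAB"``."""
    n_a, n_b = state
    if n_a < 0 or n_b < 0:
        raise ValueError(f"negative copy number in state {state!r}")
    if n_a == 0 and n_b == 0:
        return "-"  # homozygous deletion
    return "A" * n_a + "B" * n_b


def string_to_state(s: str) -> State:
    """Parse an allele string, e.g. ``"AAB" -> (2, 1)``; ``"-"`` is (0, 0)."""
    if s == "-":
        return (0, 0)
    n_a = s.count("A")
    n_b = s.count("B")
    if n_a + n_b != len(s):
        raise ValueError(f"invalid state string {s!r}")
    return (n_a, n_b)


def enumerate_states(max_cn: int = 8, include_null: bool = False) -> list[State]:
    """All states with ``n_a >= n_b`` and total copy number <= ``max_cn``.

    ``include_null`` adds the homozygous deletion (0, 0), which is excluded
    by default because its expected B-allele fraction is undefined in a pure
    tumor.
    """
    states = []
    for total in range(0 if include_null else 1, max_cn + 1):
        for n_b in range(0, total // 2 + 1):
            states.append((total - n_b, n_b))
    return states
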