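"""Stimulation/measurement protocols.

The adjacent (neighboring-pair) pattern drives electrodes (i, i+1 mod n) for
every i and senses every adjacent pair that does not touch a driving
electrode, giving n(n−3) tetrapolar measurements per condition: 504 rows for
24 electrodes, 208 for 16. The two-pole scheme drives and senses through the
same pair, which is how self- and mutual impedances are read per layer.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Protocol", "ProtocolRow", "make_protocol"]

SCHEMES = ("adjacent", "opposite", "two_pole")


@dataclass(frozen=True)
class ProtocolRow:
    drive_pos: int
    drive_neg: int
    sense_pos: int
    sense_neg: int


@dataclass(frozen=True)
class Protocol:
    rows: tuple[ProtocolRow, ...]
    current_amplitude: float  # A
    scheme: str
    n_electrodes: int

    def __len__(self) -> int:
        return len(self.rows)

    def drive_pairs(self) -> list[tuple[int, int]]:
        seen, out = set(), []
        for r in self.rows:
            p = (r.drive_pos, r.drive_neg)
            if p not in seen:
                seen.add(p)
                out.append(p)
        return out

    def sense_pairs(self) -> list[tuple[int, int]]:
        seen, out = set(), []
        for r in self.rows:
            p = (r.sense_pos, r.sense_neg)
            if p not in seen:
                seen.add(p)
                out.append(p)
        return out


def make_protocol(n_electrodes: int, scheme: str = "adjacent", current: float = 1e-3) -> Protocol:
    """Enumerate a stimulation protocol over ``n_electrodes``.

    adjacent : drive (i, i+1 mod n), sense all adjacent non-driving pairs
               → n(n−3) rows.
    opposite : drive (i, i + n/2 mod n), sense adjacent non-driving pairs.
    two_pole : drive and sense through every unordered pair (a ≤ b),
               including self-pairs.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme '{scheme}'; expected one of {SCHEMES}")
    if current <= 0:
        raise ValueError("current amplitude must be positive")
    n = n_electrodes
    rows: list[ProtocolRow] = []
    if scheme == "two_pole":
        if n < 2:
            raise ValueError("two_pole needs at least 2 electrodes")
        for a in range(n):
            for b in range(a, n):
                rows.append(ProtocolRow(a, b, a, b))
    else:
        if n < 4:
            raise ValueError("tetrapolar schemes need at least 4 electrodes")
        if scheme == "adjacent":
            drives = [(i, (i + 1) % n) for i in range(n)]
        else:  # opposite
            drives = [(i, (i + n // 2) % n) for i in range(n)]
        for dp, dn in drives:
            for j in range(n):
                sp, sn = j, (j + 1) % n
                if {sp, sn} & {dp, dn}:
                    continue
                rows.append(ProtocolRow(dp, dn, sp, sn))
    return Protocol(
        rows=tuple(rows), current_amplitude=current, scheme=scheme, n_electrodes=n
    )
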