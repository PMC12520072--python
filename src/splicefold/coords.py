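"""Site-relative coordinate convention.

Positions are counted relative to a 3' splice site with no position 0:
-1 is the acceptor G, -2 the acceptor A, -3 the N of the NAG motif, and
+1 the first exonic base.  "Upstream" always means 5' on the sense strand
(into the intron)."""

from __future__ import annotations


def rel_to_index(site_index: int, pos: int) -> int:
    """Array index of site-relative position ``pos`` (pos != 0) given the
    index of the acceptor G."""
    if pos == 0:
        raise ValueError("there is no position 0 at a splice site")
    return site_index + pos + 1 if pos < 0 else site_index + pos


def index_to_rel(site_index: int, idx: int) -> int:
    """Inverse of :func:`rel_to_index` (the G itself maps to -1)."""
    d = idx - site_index
    return d - 1 if d <= 0 else d


def rel_positions(flank: int) -> list[int]:
    """Site-relative position labels -flank..-1, +1..+flank."""
    return list(range(-flank, 0)) + list(range(1, flank + 1))
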