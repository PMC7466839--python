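"""BED / TSV track export for located elements (repeats, variants, bins).

Internal coordinates are 1-based inclusive; BED output is the package's
only 0-based half-open surface.
"""

from __future__ import annotations

from collections import namedtuple

__all__ = ["TrackItem", "write_tracks", "read_tracks"]

TrackItem = namedtuple("TrackItem", ["chrom", "start", "end", "name"])


def _as_item(obj, chrom: str) -> TrackItem:
    if isinstance(obj, TrackItem):
        return obj
    if isinstance(obj, tuple):
        return TrackItem(chrom, int(obj[0]), int(obj[1]), str(obj[2]) if len(obj) > 2 else ".")
    name = getattr(obj, "name", None) or getattr(obj, "motif", None) or getattr(obj, "unit", None)
    kind = getattr(obj, "kind", None)
    label = str(name if name is not None else (kind if kind is not None else "."))
    start = getattr(obj, "start", None)
    if start is None:
        start = obj.pos1
        end = start + obj.len - 1
    else:
        end = obj.end
    return TrackItem(chrom, int(start), int(end), label)


def write_tracks(items, path, fmt: str = "TSV", chrom: str = "plastome") -> None:
    """Write located elements as a BED or TSV track.

    BED converts to 0-based half-open coordinates; TSV keeps 1-based
    inclusive coordinates.  An empty item list yields a header-only file.
    """
    fmt = fmt.upper()
    if fmt not in ("BED", "TSV"):
        raise ValueError(f"unknown track format {fmt!r}")
    rows = [_as_item(it, chrom) for it in items]
    with open(path, "w") as fh:
        if fmt == "TSV":
            fh.write("# chrom\tstart\tend\tname\t(1-based inclusive)\n")
            for r in rows:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")
        else:
            fh.write("# chrom\tchromStart\tchromEnd\tname\t(0-based half-open)\n")
            for r in rows:
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.name}\n")


def read_tracks(path, fmt: str = "TSV") -> list[TrackItem]:
    """Read a track file back into 1-based inclusive :class:`TrackItem`s."""
    fmt = fmt.upper()
    items = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, name = line.rstrip("\n").split("\t")[:4]
            start, end = int(start), int(end)
            if fmt == "BED":
                start += 1
            items.append(TrackItem(chrom, start, end, name))
    return items
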