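"""Saturation-offset schemes for CEST Z-spectrum acquisitions.

A Z-spectrum acquisition is a list of saturated frames, each tagged with a
frequency offset in ppm relative to water, plus one unsaturated reference
frame used for normalisation.  Several offsets — notably those around the
amide resonance at +/-3.5 ppm — are acquired repeatedly to boost SNR, so the
scheme stores ``(offset_ppm, repetitions)`` pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["OffsetScheme", "default_offset_scheme", "parse_offset_scheme"]

#: frame label used for the unsaturated normalisation image
REFERENCE_LABEL = "S0"


@dataclass(frozen=True)
class OffsetScheme:
    """Ordered saturation offsets with repetition counts plus a reference frame.

    Parameters
    ----------
    entries:
        ``(offset_ppm, repetitions)`` in acquisition order.
    has_reference:
        Whether an unsaturated reference frame is part of the acquisition.
    """

    entries: tuple[tuple[float, int], ...]
    has_reference: bool = True

    def __post_init__(self) -> None:
        for off, rep in self.entries:
            if rep < 1:
                raise ValueError(f"repetition count must be >= 1 at offset {off}")

    @property
    def n_saturated(self) -> int:
        return sum(rep for _, rep in self.entries)

    @property
    def n_frames(self) -> int:
        """Total acquisition length (saturated frames + reference)."""
        return self.n_saturated + int(self.has_reference)

    @property
    def unique_offsets(self) -> list[float]:
        """Sorted unique offsets (ppm)."""
        return sorted({off for off, _ in self.entries})

    def frame_offsets(self) -> list[float | None]:
        """Per-frame offset in acquisition order; ``None`` marks the reference.

        The reference frame is emitted first, matching the convention that the
        normalisation image is acquired before the saturated sweep.
        """
        frames: list[float | None] = [None] if self.has_reference else []
        for off, rep in self.entries:
            frames.extend([off] * rep)
        return frames


def default_offset_scheme() -> OffsetScheme:
    """The 63-frame acquisition scheme used throughout this package.

    One unsaturated reference frame plus 62 saturated frames: a sparse
    positive-only far wing (80 ... 10 ppm), symmetric pairs through the
    exchange-sensitive region with the amide offsets +/-3.5 ppm repeated six
    times each, and the on-resonance 0 ppm frame.
    """
    entries: list[tuple[float, int]] = [
        (80.0, 1), (70.0, 1), (60.0, 1), (50.0, 1), (40.0, 1),
        (30.0, 1), (20.0, 1), (15.625, 1), (10.0, 1),
    ]
    paired: list[tuple[float, int]] = [
        (6.0, 1), (5.0, 1), (4.5, 1), (4.0, 2), (3.75, 2), (3.5, 6),
        (3.25, 2), (3.0, 2), (2.5, 2), (2.0, 2), (1.5, 1), (1.0, 1),
        (0.75, 1), (0.5, 1), (0.25, 1),
    ]
    for off, rep in paired:
        entries.append((off, rep))
        entries.append((-off, rep))
    entries.append((0.0, 1))
    return OffsetScheme(entries=tuple(entries), has_reference=True)


def parse_offset_scheme(frame_labels: list[str | float | None]) -> OffsetScheme:
    """Build an :class:`OffsetScheme` from per-frame labels.

    Parameters
    ----------
    frame_labels:
        One label per acquired frame, in order.  The reference frame is
        labelled ``"S0"`` (or ``None``); every other label must parse as a
        frequency offset in ppm.  Repeated offsets are collapsed into a
        repetition count.

    Raises
    ------
    ValueError
        If no reference frame is present, or a label is unparseable.
    """
    counts: dict[float, int] = {}
    order: list[float] = []
    n_reference = 0
    for label in frame_labels:
        if label is None or (isinstance(label, str) and label.strip().upper() == REFERENCE_LABEL):
            n_reference += 1
            continue
        try:
            off = float(label)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"unparseable frame label: {label!r}") from exc
        if off not in counts:
            counts[off] = 0
            order.append(off)
        counts[off] += 1
    if n_reference == 0:
        raise ValueError("no unsaturated reference (S0) frame in the frame list")
    if n_reference > 1:
        raise ValueError(f"expected exactly one reference frame, found {n_reference}")
    return OffsetScheme(entries=tuple((off, counts[off]) for off in order), has_reference=True)
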