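"""The 96 single-base-substitution trinucleotide channels.

Channels follow the standard ordering: six pyrimidine substitution
classes (C>A, C>G, C>T, T>A, T>C, T>G), each split into 16 trinucleotide
contexts grouped by the base 5' of the mutated base and, within each
group, by the 3' base, both in the order A, C, G, T. Mutations with a
purine reference base are reported on the reverse complement
(pyrimidine-strand convention).
"""

from __future__ import annotations

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def channels_96() -> list[str]:
    """Return the 96 channel labels, e.g. ``A[C>A]A``, in canonical order."""
    out = []
    for sub in SUBSTITUTIONS:
        for five in BASES:
            for three in BASES:
                out.append(f"{five}[{sub}]{three}")
    return out


CHANNELS_96 = tuple(channels_96())
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def channel_of(context: str, alt: str) -> str:
    """Map a trinucleotide context and alternate base to a channel label.

    Parameters
    ----------
    context
        Three reference bases centred on the mutated base.
    alt
        Alternate base of the mutated (central) position.
    """
    context = context.upper()
    alt = alt.upper()
    if len(context) != 3:
        raise ValueError(f"context must be a trinucleotide, got {context!r}")
    ref = context[1]
    if ref == alt:
        raise ValueError(f"ref and alt are both {ref!r}")
    if ref in ("G", "A"):  # purine reference: flip to the pyrimidine strand
        context = reverse_complement(context)
        alt = _COMPLEMENT[alt]
        ref = context[1]
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    if label not in _CHANNEL_INDEX:
        raise ValueError(f"invalid channel {label!r} (ambiguous base?)")
    return label


def channel_index(channel: str) -> int:
    """0-based position of a channel label in the canonical ordering."""
    try:
        return _CHANNEL_INDEX[channel]
    except KeyError:
        raise ValueError(f"unknown channel {channel!r}") from None
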