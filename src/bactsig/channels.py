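"""Single-base-substitution channel definitions and sequence encoding.

The 96-channel classification represents every base-pair substitution by the
strand on which the mutated base is a pyrimidine: six substitution classes
(C>A, C>G, C>T, T>A, T>C, T>G) times 16 combinations of the 5' and 3'
flanking bases. Channel order is the canonical COSMIC order: substitution
classes in the order above, flanking bases alphabetical (5' major, 3' minor),
with labels like ``A[C>A]A``.

The stranded (192-channel) classification prefixes each channel with ``T:``
(transcribed, pyrimidine on the template strand of the overlapping gene under
the default convention) or ``U:`` (untranscribed).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Six strand-collapsed base-pair substitution types, in the conventional
#: reporting order (transitions first).
SIX_TYPES = ("G:C>A:T", "A:T>G:C", "G:C>T:A", "G:C>C:G", "A:T>T:A", "A:T>C:G")

_PYR_SUB_TO_SIX = {
    "C>T": "G:C>A:T",
    "T>C": "A:T>G:C",
    "C>A": "G:C>T:A",
    "C>G": "G:C>C:G",
    "T>A": "A:T>T:A",
    "T>G": "A:T>C:G",
}

#: The 96 channels in canonical COSMIC order.
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)
CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}

#: The 32 pyrimidine-centered trinucleotide contexts (C-centered block first,
#: flanks alphabetical within each block).
CONTEXTS_32 = tuple(
    five + center + three for center in "CT" for five in BASES for three in BASES
)
CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_32)}

#: Stranded channels: transcribed block then untranscribed block, each in
#: canonical 96-channel order.
STRANDED_CHANNELS_192 = tuple(
    f"{lab}:{c}" for lab in ("T", "U") for c in CHANNELS_96
)


def _channel_context(label: str) -> str:
    five, ref, _, three = parse_channel(label)
    return five + ref + three


def parse_channel(label: str) -> tuple[str, str, str, str]:
    """Split ``"A[C>T]G"`` into ``("A", "C", "T", "G")``."""
    five = label[0]
    ref = label[2]
    alt = label[4]
    three = label[6]
    return five, ref, alt, three


#: Per-channel pyrimidine-centered context string / index.
CHANNEL_CONTEXT = tuple(_channel_context(c) for c in CHANNELS_96)
CHANNEL_TO_CONTEXT = np.array(
    [CONTEXT_INDEX[ctx] for ctx in CHANNEL_CONTEXT], dtype=np.int64
)


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def channel_of(ref: str, alt: str, five: str, three: str) -> str:
    """Pyrimidine-collapsed channel for a substitution with its genomic flanks.

    ``five``/``three`` are the bases flanking the mutated position on the
    forward (reference) strand. If the reference base is a purine, the whole
    rendering is reverse-complemented so the mutated base is a pyrimidine.
    """
    if ref in PYRIMIDINES:
        return f"{five}[{ref}>{alt}]{three}"
    return (
        f"{COMPLEMENT[three]}[{COMPLEMENT[ref]}>{COMPLEMENT[alt]}]{COMPLEMENT[five]}"
    )


def six_type_of(ref: str, alt: str) -> str:
    """Strand-collapsed six-type label (e.g. G>A and C>T both → G:C>A:T)."""
    if ref in PYRIMIDINES:
        sub = f"{ref}>{alt}"
    else:
        sub = f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}"
    return _PYR_SUB_TO_SIX[sub]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes A=0, C=1, G=2, T=3; others=255.

    Complementation is ``3 - code`` for valid codes.
    """
    table = np.full(256, 255, dtype=np.uint8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def genome_context_table(code: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pyrimidine-collapsed context id and pyrimidine strand per position.

    Returns ``(ctx, pyr_forward)`` where ``ctx[i]`` is the index into
    :data:`CONTEXTS_32` of the collapsed trinucleotide centered at 0-based
    position ``i`` (−1 at the two terminal positions and wherever the window
    contains a non-ACGT base), and ``pyr_forward[i]`` is True when the center
    base is a pyrimidine on the forward strand.
    """
    L = len(code)
    ctx = np.full(L, -1, dtype=np.int16)
    pyr_forward = np.zeros(L, dtype=bool)
    if L < 3:
        return ctx, pyr_forward
    five = code[:-2].astype(np.int16)
    cen = code[1:-1].astype(np.int16)
    three = code[2:].astype(np.int16)
    ok = (five < 4) & (cen < 4) & (three < 4)
    is_pyr = (cen == 1) | (cen == 3)  # C or T
    # collapsed center: C-block (0) or T-block (1)
    cen_col = np.where(is_pyr, (cen == 3), (cen == 0)).astype(np.int16)
    f = np.where(is_pyr, five, 3 - three)
    t = np.where(is_pyr, three, 3 - five)
    inner = cen_col * 16 + f * 4 + t
    ctx[1:-1][ok] = inner[ok]
    pyr_forward[1:-1] = is_pyr & ok
    return ctx, pyr_forward
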