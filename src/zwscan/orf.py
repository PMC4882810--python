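"""Open-reading-frame discovery and SNP coding-effect classification.

ORFs are scanned in all three frames on both strands of each transcript. An
ORF runs from an ATG — or from the contig edge, in which case it is
5'-partial — to the first in-frame stop codon (TAA/TAG/TGA), or to the
contig edge (3'-partial). Assembled transcripts frequently truncate real
coding sequence, so partial ORFs are first-class citizens. Transcripts are
retained as protein-coding when their longest ORF exceeds a minimum length
(strictly more than 100 amino acids by default, stop codon excluded).

Variants inside a retained ORF are classified synonymous or nonsynonymous
by substituting the allele into its codon and translating with the standard
genetic code (a stop counts as an amino-acid state, so stop-gain/loss is
nonsynonymous); variants outside are noncoding. Codons containing N are
untranslatable: substitutions in them are reported as ``indeterminate`` and
excluded from amino-acid-change counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# standard genetic code; '*' is the stop state
_AA = (
    "KNKNTTTTRSRSIIMIQHQHPPPPRRRRLLLL"
    "EDEDAAAAGGGGVVVV*Y*YSSSS*CWCLFLF"
)
_ORDER = "ACGT"
CODON_TABLE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_ORDER)
    for j, b in enumerate(_ORDER)
    for k, c in enumerate(_ORDER)
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

EFFECT_CODES = {
    "synonymous": "SYN",
    "nonsynonymous": "NSY",
    "noncoding": "NCD",
    "indeterminate": "IND",
}


def translate_codon(codon: str) -> str:
    """Single-codon translation; codons containing N (or short) give X."""
    codon = codon.upper()
    return CODON_TABLE.get(codon, "X")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Orf:
    """One open reading frame on a transcript.

    ``start``/``end`` are 0-based half-open coordinates on the forward
    strand regardless of ``strand``; ``end`` includes the stop codon when
    one is present (``partial3`` false). ``aa_length`` excludes the stop.
    """

    transcript_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    frame: int  # 0-2, offset on the scanned strand
    partial5: bool
    partial3: bool
    aa_length: int

    @property
    def complete(self) -> bool:
        return not (self.partial5 or self.partial3)


@dataclass(frozen=True)
class VariantEffect:
    """Predicted coding consequence of a single-nucleotide substitution."""

    pos: int
    ref: str
    alt: str
    effect: str  # synonymous | nonsynonymous | noncoding | indeterminate
    codon_ref: str | None = None
    codon_alt: str | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None

    @property
    def code(self) -> str:
        return EFFECT_CODES[self.effect]


def _scan_strand(seq: str, strand: str, length: int, transcript_id: str) -> list[Orf]:
    """All maximal ORFs on one strand; seq is already strand-oriented."""
    orfs = []
    for frame in range(3):
        n_codons = (length - frame) // 3
        if n_codons <= 0:
            continue
        codons = [seq[frame + 3 * i : frame + 3 * i + 3] for i in range(n_codons)]
        chunk_start = 0
        k = 0
        while chunk_start < n_codons:
            # next in-frame stop; codons with N never match stop
            stop = next(
                (k for k in range(chunk_start, n_codons) if codons[k] in STOP_CODONS),
                None,
            )
            chunk_end = stop if stop is not None else n_codons
            at_edge = chunk_start == 0
            if at_edge:
                start_codon = chunk_start
                partial5 = codons[chunk_start] != "ATG"
            else:
                start_codon = next(
                    (k for k in range(chunk_start, chunk_end) if codons[k] == "ATG"),
                    None,
                )
                partial5 = False
            if start_codon is not None and chunk_end > start_codon:
                s = frame + 3 * start_codon
                if stop is not None:
                    e = frame + 3 * (stop + 1)  # include the stop codon
                    aa = (e - s) // 3 - 1
                    partial3 = False
                else:
                    e = frame + 3 * chunk_end
                    aa = (e - s) // 3
                    partial3 = True
                if aa >= 1:
                    if strand == "+":
                        fs, fe = s, e
                    else:
                        fs, fe = length - e, length - s
                    orfs.append(
                        Orf(transcript_id, fs, fe, strand, frame, partial5, partial3, aa)
                    )
            if stop is None:
                break
            chunk_start = stop + 1
    return orfs


def _sort_key(o: Orf):
    # longest first; ties: complete before partial, then + strand, then leftmost
    return (-o.aa_length, not o.complete, o.strand != "+", o.start)


def find_orfs(seq: str, transcript_id: str = "") -> list[Orf]:
    """All maximal ORFs of a transcript, longest first.

    Maximal means not contained (by forward-strand interval, same strand)
    in a longer-or-equal ORF; an edge-to-stop partial ORF therefore
    supersedes any ATG-to-stop ORF nested inside it.
    """
    seq = seq.upper()
    if not seq:
        return []
    length = len(seq)
    raw = _scan_strand(seq, "+", length, transcript_id) + _scan_strand(
        reverse_complement(seq), "-", length, transcript_id
    )
    raw.sort(key=_sort_key)
    kept: list[Orf] = []
    for o in raw:
        contained = any(
            k.strand == o.strand and k.start <= o.start and o.end <= k.end for k in kept
        )
        if not contained:
            kept.append(o)
    return kept


def filter_orfs(
    orfs_by_transcript: dict[str, list[Orf]], min_aa: int = 100
) -> dict[str, Orf]:
    """Keep the single best ORF per transcript with aa_length > ``min_aa``.

    The length comparison is strict; transcripts with no qualifying ORF are
    absent from the result (non-coding).
    """
    retained: dict[str, Orf] = {}
    for tid, orfs in orfs_by_transcript.items():
        qualifying = [o for o in orfs if o.aa_length > min_aa]
        if qualifying:
            retained[tid] = min(qualifying, key=_sort_key)
    return retained


def classify_variant_effect(
    seq: str, orf: Orf | None, pos: int, ref: str, alt: str
) -> VariantEffect:
    """Coding effect of substituting ``alt`` for ``ref`` at ``pos``.

    ``pos``/``ref``/``alt`` are forward-strand; minus-strand ORFs are
    handled by complementing into ORF orientation. ``orf=None`` means the
    transcript was not retained as coding, so every site is noncoding.
    """
    seq = seq.upper()
    ref, alt = ref.upper(), alt.upper()
    if not 0 <= pos < len(seq):
        raise ValueError(f"position {pos} outside transcript of length {len(seq)}")
    if seq[pos] != ref:
        raise ValueError(f"reference mismatch at {pos}: sequence has {seq[pos]}, got {ref}")
    if alt == ref:
        raise ValueError("alt equals ref")
    if orf is None or not (orf.start <= pos < orf.end):
        return VariantEffect(pos, ref, alt, "noncoding")

    if orf.strand == "+":
        oriented = seq
        opos = pos
        ostart = orf.start
        oalt = alt
    else:
        oriented = reverse_complement(seq)
        opos = len(seq) - 1 - pos
        ostart = len(seq) - orf.end
        oalt = alt.translate(_COMPLEMENT)
    codon_idx = (opos - ostart) // 3
    cs = ostart + 3 * codon_idx
    codon_ref = oriented[cs : cs + 3]
    offset = opos - cs
    codon_alt = codon_ref[:offset] + oalt + codon_ref[offset + 1 :]
    if len(codon_ref) < 3 or "N" in codon_ref:
        return VariantEffect(pos, ref, alt, "indeterminate", codon_ref, codon_alt)
    aa_ref = translate_codon(codon_ref)
    aa_alt = translate_codon(codon_alt)
    effect = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
    return VariantEffect(pos, ref, alt, effect, codon_ref, codon_alt, aa_ref, aa_alt)


def annotate_variants(
    sites: pd.DataFrame,
    sequences: dict[str, str],
    retained: dict[str, Orf],
) -> pd.Series:
    """Effect label per variant row (columns contig/pos/ref/alt).

    Returns a Series of effect names aligned with ``sites``.
    """
    labels = []
    for site in sites.itertuples(index=False):
        eff = classify_variant_effect(
            sequences[site.contig], retained.get(site.contig), site.pos, site.ref, site.alt
        )
        labels.append(eff.effect)
    return pd.Series(labels, index=sites.index, name="effect")


def orf_table(retained: dict[str, Orf]) -> pd.DataFrame:
    """Retained ORFs as a tidy table (for the TSV interface)."""
    rows = [
        {
            "transcript_id": o.transcript_id,
            "start": o.start,
            "end": o.end,
            "strand": o.strand,
            "aa_length": o.aa_length,
            "partial5": o.partial5,
            "partial3": o.partial3,
        }
        for o in retained.values()
    ]
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "start", "end", "strand", "aa_length", "partial5", "partial3"],
    )
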