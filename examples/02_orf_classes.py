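"""Enumerate and classify rolling-circle ORFs on four tiny circles.

A ribosome on a covalently closed circle can read through the backsplice
junction, so an ORF is classified by how many times it crosses the
junction: 0C never crosses, 1C once (gaining a novel N or C terminus),
2C twice or more (novel at both ends), and edlsC endless — a stop-free
reading frame whose ORF is infinite and whose peptide is a repeat of one
minimal period.
"""

from circkit.orfs import CircularSequence, enumerate_orfs

EXAMPLES = {
    "ATGAAATAA": "plain linear ORF, never reaches the junction",
    "TAAATGCCC": "start near the 3' end, reads once across the junction",
    "ATGAAAAAAA": "stop only appears after two passes of the junction",
    "ATGGCTGCT": "stop-free frame: the ORF is endless (rolling circle)",
}

for seq, why in EXAMPLES.items():
    print(f"circle {seq} (L={len(seq)}): {why}")
    for o in enumerate_orfs(CircularSequence(seq, [], "+")):
        crossings = "inf" if o.crossings is None else o.crossings
        length = "inf" if o.endless else o.length_nt
        print(
            f"  start={o.start} length_nt={length} crossings={crossings} "
            f"class={o.orf_class} peptide={o.peptide}"
        )
    print()
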