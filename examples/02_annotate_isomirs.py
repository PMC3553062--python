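"""Match tags against a mature-miRNA catalog and name their variants.

IsomiR names encode the differences from the reference mature: _L+1 means
one extra 5' base, _R-2 a 2-nt-shorter 3' end, _1ss21TC a T->C substitution
at tag position 21.
"""

from mircms import MatureRecord, match_mature

catalog = [
    MatureRecord("ath-miR156h", "TGACAGAAGAAAGAGAGCAC"),
    MatureRecord("ahy-miR167-5p", "TGAAGCTGCCAGCATGATCTT"),
    MatureRecord("ath-miR159c", "TTTGGATTGAAGGGAGCTCTA"),
]

observed = [
    "TGACAGAAGAAAGAGAGCAC",    # exact reference
    "TTGACAGAAGAAAGAGAGCAC",   # one extra 5' base
    "TGAAGCTGCCAGCATGATCTC",   # terminal T->C substitution
    "TTTGGATTGAAGGGAGCTC",     # 3' end two bases short
]

for tag in observed:
    hit = match_mature(tag, catalog)
    print(f"{tag:>24} -> {hit.assigned_name}")
# Each assigned name pinpoints the edit; an exact match carries no suffix.
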