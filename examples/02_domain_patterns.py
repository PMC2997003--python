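"""Parse PROSITE-style patterns and scan sequences for signature motifs.

The class-1 aaRS adenylate-binding site carries the HIGH peptide; the
pattern matcher locates it (1-based positions) and scan_sequences turns
matches into a domain annotation.
"""

from aarspred import ProteinSequence, parse_prosite_pattern, match_pattern
from aarspred.domains import scan_sequences, BUILTIN_PATTERNS

pat = parse_prosite_pattern("H-I-G-H.", "PS00178")
seq = ProteinSequence("q1", "MAHIGHKMSKSLLHIGHW")
print("HIGH matches at positions:", match_pattern(pat, seq))

fancy = parse_prosite_pattern("[HK]-x(1,2)-G-{P}.")
print("set/wildcard/exclusion pattern matches:", match_pattern(fancy, seq))

ann = scan_sequences([seq, ProteinSequence("q2", "ACDEFGACDEFG")],
                     BUILTIN_PATTERNS)
print("internal scan:", {k: sorted(v) for k, v in ann.hits.items()})
# q1 gets PS00178 from its HIGH signature; q2 has no detectable domain.
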