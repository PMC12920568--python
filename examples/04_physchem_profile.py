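"""Profile the eight physicochemical properties of a peptide set.

Computes GRAVY, molecular weight, aromaticity, instability index, pI,
net charge at pH 7, Boman index and tryptophan content for a handful of
peptides, and shows the min-max-normalized matrix used for heat-map style
comparison.
"""

from orf2pep.physchem import profile_peptides
from orf2pep.seqio import PeptideRecord

peptides = [
    PeptideRecord(id="cationic", sequence="KWKLFKKIGAVLKVL"),   # magainin-like
    PeptideRecord(id="acidic", sequence="DDEEDNSAGGDD"),
    PeptideRecord(id="hydrophobic", sequence="LLVVAAILGAVLIV"),
    PeptideRecord(id="aromatic", sequence="WWFYRWFWRRWF"),
]

matrix = profile_peptides(peptides)
print("raw properties:")
print(matrix.raw.round(2).to_string())
print("\nmin-max normalized (0 = column minimum, 1 = column maximum):")
print(matrix.normalized.round(2).to_string())
# The cationic and aromatic peptides show the high pI / net charge / Boman
# profile typical of anticancer candidates, while the hydrophobic peptide
# has the high-GRAVY signature associated with membrane-active AMPs.
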