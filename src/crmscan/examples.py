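"""Worked-example inputs: the rpr-HRE-571 enhancer coordinates and EMSA probes.

The *Drosophila melanogaster* pro-apoptotic gene *reaper* (*rpr*) is
repressed in posterior-spiracle precursor cells by the transcription factor
Cut acting on a 571 bp enhancer element (rpr-HRE-571) on chromosome arm 3L,
about 6 kb downstream of the *rpr* coding sequence.  The element was found
by searching for clusters of Abdominal-B binding sites (>= 3 sites in a
400 bp window) inside highly conserved non-coding sequence.

The S2 sub-fragment of this enhancer carries three Cut binding sites; in
electrophoretic mobility shift assays the mutated probe substitutes two
bases (TC -> GG) in each of the three sites, abolishing Cut binding.  The
forward-strand probe sequences are 53 nt each.
"""

RPR_HRE_571_COORDS = "3L:18384438..18385008"

S2_PROBE_WT = "GCACTTTTGCCTGCAGTTCAACTCGGTTCAGTTCGGTTGTGTCATAAAAAATC"
S2_PROBE_MUT = "GCACTTTTGCCTGCAGTGGAACTCGGTGGAGTGGGGTTGTGTCATAAAAAATC"
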