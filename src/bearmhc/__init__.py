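"""bearmhc: MHC amplicon genotyping, allele validation and selection analysis.

Pipeline stages: simulate (ground-truthed amplicon data) -> genotype
(demultiplex + MPAF allele validation) -> express (gDNA/cDNA comparison)
-> molevol (distances, Nei-Gojobori dN/dS, selection Z tests) ->
popstruct (dominant-marker AMOVA FST).
"""

from importlib import resources

__version__ = "0.1.0"


def data_path(name: str):
    """Path to a bundled data file (presence table, ABS masks)."""
    return resources.files("bearmhc") / "data" / name
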