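"""Canonical assay and condition labels used across the pipeline."""

CONTROL = "F/F"      # parental / wild-type condition
MUTANT = "FC/FC"     # MLL2-excised condition

GH2AX = "gH2AX"      # phospho-H2AX ChIP, DNA-damage proxy
H2AX = "H2AX"        # unphosphorylated H2AX ChIP control
H3 = "H3"            # histone H3 ChIP, nucleosome-density normalizer
RNAPII = "RNAPII"    # RNA polymerase II ChIP
GRO = "GRO"          # nuclear run-on (nascent transcription), stranded

ASSAYS = (GH2AX, H2AX, H3, RNAPII, GRO)
CONDITIONS = (CONTROL, MUTANT)

# filename-safe condition tokens for on-disk track names
CONDITION_TOKENS = {CONTROL: "FF", MUTANT: "FCFC"}
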