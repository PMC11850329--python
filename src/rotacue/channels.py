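"""Electrode montage used by the simulated recordings.

60 EEG channels in 10-10 positions plus 4 periocular EOG electrodes
(outer canthi left/right, above/below the left eye).
"""

EEG_CHANNELS = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "O2",
)

EOG_CHANNELS = ("EOGL", "EOGR", "EOGU", "EOGD")

#: Channels over central motor areas used for waveform-similarity analyses.
CENTRAL_CHANNELS = (
    "FC3", "FC1", "FCz", "FC2", "FC4",
    "C3", "C1", "Cz", "C2", "C4",
    "CP3", "CP1", "CPz", "CP2", "CP4",
)

assert len(EEG_CHANNELS) == 60
assert len(set(EEG_CHANNELS)) == 60
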