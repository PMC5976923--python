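"""Recording geometry and paradigm constants for the RSVP ERP speller.

Eleven electrodes of the international 10/20 system are recorded at 256 Hz.
Epochs are stimulus-locked windows of 300 samples (~1.17 s), longer than the
300 ms inter-stimulus interval; overlap with subsequent stimuli is not
modelled by the simulator.
"""

SFREQ_HZ = 256.0
N_SAMPLES = 300
N_CHANNELS = 11

#: Channel order is fixed everywhere: frontal, central, parietal, occipital.
CHANNELS = ("F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4", "O1", "O2")

N_ICONS = 6
N_REPETITIONS = 20          # presentations of each icon per trial
TRIALS_PER_SESSION = 12
ISI_S = 0.300

#: Rows of the wrapped CNN input: 11 channels + the 3 frontal rows repeated
#: at the bottom so a 6-row spatial filter sees occipital-frontal adjacency.
N_INPUT_ROWS = 14

EPOCH_DURATION_S = N_SAMPLES / SFREQ_HZ


def sample_times() -> "numpy.ndarray":  # noqa: F821 - annotation only
    """Times (s, post stimulus onset) of the 300 epoch samples."""
    import numpy as np

    return np.arange(N_SAMPLES) / SFREQ_HZ
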