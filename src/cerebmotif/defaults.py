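"""Central registry of default parameter values.

Every tunable constant used across the package lives here so that the
analysis defaults and the synthetic-data generators stay in sync.  Values
are measured quantities from the study system where one exists (IPSC
amplitude, stimulus duration, anatomical thresholds) and conventional
analysis choices otherwise.
"""

# --- optogenetic stimulation -------------------------------------------------
STIM_DURATION_MS: float = 3.0      # duration of the light pulse
STIM_ONSET_MS: float = 20.0        # default onset within a simulated sweep

# --- IPSC feature extraction -------------------------------------------------
BASELINE_WINDOW_MS: float = 10.0   # pre-stimulus window for baseline/noise SD
RESPONSE_WINDOW_MS: float = 50.0   # post-onset window searched for the peak
DETECTION_THRESHOLD_SD: float = 3.0  # success if amplitude >= theta * noise SD
DETECTION_SMOOTH_MS: float = 0.5   # boxcar applied before success detection
SUCCESS_FRACTION: float = 0.5      # lobule responsive if >= this success rate
MIN_SWEEPS: int = 3                # trials required per stimulation site

# --- spike-train analysis ----------------------------------------------------
MIN_FIRING_RATE_HZ: float = 20.0   # trials below this rate are excluded
BURST_CV_MAX: float = 1.0          # ISI CV above this marks a bursting trial

# --- bootstrap topography ----------------------------------------------------
BOOTSTRAP_ITERATIONS: int = 50_000
BOOTSTRAP_ALPHA: float = 0.05

# --- puncta geometry ---------------------------------------------------------
SOMA_DIAMETER_UM: float = 17.5     # average CN soma diameter
DENDRITE_LENGTH_UM: float = 100.5  # average CN dendrite length

# --- synthetic-data generator defaults ---------------------------------------
SIM_IPSC_AMPLITUDE_PA: float = 91.18   # mean lobule-evoked IPSC amplitude
SIM_TERMINAL_AMPLITUDE_PA: float = 340.82
SIM_RISE_TAU_MS: float = 0.8
SIM_DECAY_TAU1_MS: float = 3.0
SIM_DECAY_TAU2_MS: float = 15.0
SIM_DECAY_FRAC1: float = 0.67          # weight of the fast decay component
SIM_NOISE_SD_PA: float = 2.0
SIM_SAMPLING_INTERVAL_MS: float = 0.1
SIM_SWEEP_DURATION_MS: float = 150.0
SIM_FIRING_RATE_HZ: float = 50.0       # tonic CN firing, comfortably >= 20 Hz
SIM_ISI_CV: float = 0.2                # regular (non-bursting) tonic firing
SIM_PAUSE_FACTOR: float = 1.5
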