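{
  "_comment": "Canonical registry of acoustic speech features. Keys are canonical ids '<base>_<task>' with task a=sustained /a/, s=syllable repetition, m=monologue, t=reading passage. 'direction' is the impairment orientation of the z-score: +1 when higher raw values indicate worse speech, -1 when lower raw values indicate worse speech. 'subsystem' follows the speech-production subsystem the feature probes; 'dysarthria_type' is the subtype whose perceptual correlate the feature targets.",
  "features": {
    "RLR_m":    {"base": "RLR",    "task": "m", "unit": "dB",            "direction": -1, "subsystem": "respiration",  "dysarthria_type": "hypokinetic", "description": "relative loudness of respiration"},
    "RLR_t":    {"base": "RLR",    "task": "t", "unit": "dB",            "direction": -1, "subsystem": "respiration",  "dysarthria_type": "hypokinetic", "description": "relative loudness of respiration"},
    "RSR_m":    {"base": "RSR",    "task": "m", "unit": "ms",            "direction": 1,  "subsystem": "respiration",  "dysarthria_type": "hypokinetic", "description": "rate of speech respiration"},
    "RSR_t":    {"base": "RSR",    "task": "t", "unit": "ms",            "direction": 1,  "subsystem": "respiration",  "dysarthria_type": "hypokinetic", "description": "rate of speech respiration"},
    "PIR_m":    {"base": "PIR",    "task": "m", "unit": "pauses/resp",   "direction": -1, "subsystem": "respiration",  "dysarthria_type": "hypokinetic", "description": "pause intervals per respiration"},
    "PIR_t":    {"base": "PIR",    "task": "t", "unit": "pauses/resp",   "direction": -1, "subsystem": "respiration",  "dysarthria_type": "hypokinetic", "description": "pause intervals per respiration"},
    "jitter_a": {"base": "jitter", "task": "a", "unit": "%",             "direction": 1,  "subsystem": "phonation",    "dysarthria_type": "hypokinetic", "description": "short-time fundamental-period perturbation"},
    "shimmer_a":{"base": "shimmer","task": "a", "unit": "%",             "direction": 1,  "subsystem": "phonation",    "dysarthria_type": "hypokinetic", "description": "cycle-to-cycle amplitude perturbation"},
    "HNR_a":    {"base": "HNR",    "task": "a", "unit": "dB",            "direction": -1, "subsystem": "phonation",    "dysarthria_type": "hypokinetic", "description": "harmonics-to-noise ratio"},
    "GVI_m":    {"base": "GVI",    "task": "m", "unit": "pauses/min",    "direction": -1, "subsystem": "phonation",    "dysarthria_type": "hypokinetic", "description": "gaping in-between voiced intervals"},
    "GVI_t":    {"base": "GVI",    "task": "t", "unit": "pauses/min",    "direction": -1, "subsystem": "phonation",    "dysarthria_type": "hypokinetic", "description": "gaping in-between voiced intervals"},
    "DUS_m":    {"base": "DUS",    "task": "m", "unit": "ms",            "direction": 1,  "subsystem": "articulation", "dysarthria_type": "hypokinetic", "description": "duration of stop consonants"},
    "DUS_t":    {"base": "DUS",    "task": "t", "unit": "ms",            "direction": 1,  "subsystem": "articulation", "dysarthria_type": "hypokinetic", "description": "duration of stop consonants"},
    "VOT_s":    {"base": "VOT",    "task": "s", "unit": "ms",            "direction": 1,  "subsystem": "articulation", "dysarthria_type": "hypokinetic", "description": "voice onset time"},
    "RFA_m":    {"base": "RFA",    "task": "m", "unit": "dB",            "direction": 1,  "subsystem": "articulation", "dysarthria_type": "hypokinetic", "description": "resonance frequency attenuation"},
    "RFA_t":    {"base": "RFA",    "task": "t", "unit": "dB",            "direction": 1,  "subsystem": "articulation", "dysarthria_type": "hypokinetic", "description": "resonance frequency attenuation"},
    "DPI_m":    {"base": "DPI",    "task": "m", "unit": "ms",            "direction": 1,  "subsystem": "timing",       "dysarthria_type": "hypokinetic", "description": "duration of pause intervals"},
    "DPI_t":    {"base": "DPI",    "task": "t", "unit": "ms",            "direction": 1,  "subsystem": "timing",       "dysarthria_type": "hypokinetic", "description": "duration of pause intervals"},
    "EST_m":    {"base": "EST",    "task": "m", "unit": "bits",          "direction": -1, "subsystem": "timing",       "dysarthria_type": "hypokinetic", "description": "entropy of speech timing"},
    "EST_t":    {"base": "EST",    "task": "t", "unit": "bits",          "direction": -1, "subsystem": "timing",       "dysarthria_type": "hypokinetic", "description": "entropy of speech timing"},
    "RST_m":    {"base": "RST",    "task": "m", "unit": "intervals/min", "direction": -1, "subsystem": "timing",       "dysarthria_type": "hypokinetic", "description": "rate of speech timing"},
    "RST_t":    {"base": "RST",    "task": "t", "unit": "intervals/min", "direction": -1, "subsystem": "timing",       "dysarthria_type": "hypokinetic", "description": "rate of speech timing"},
    "AST_t":    {"base": "AST",    "task": "t", "unit": "permil/min^2",  "direction": -1, "subsystem": "timing",       "dysarthria_type": "hypokinetic", "description": "acceleration of speech timing"},
    "stdF0_m":  {"base": "stdF0",  "task": "m", "unit": "semitones",     "direction": -1, "subsystem": "prosody",      "dysarthria_type": "hypokinetic", "description": "pitch variability of connected speech"},
    "stdF0_t":  {"base": "stdF0",  "task": "t", "unit": "semitones",     "direction": -1, "subsystem": "prosody",      "dysarthria_type": "hypokinetic", "description": "pitch variability of connected speech"},
    "stdF0_a":  {"base": "stdF0",  "task": "a", "unit": "semitones",     "direction": 1,  "subsystem": "phonation",    "dysarthria_type": "ataxic",      "description": "pitch fluctuation of sustained phonation"},
    "stdPSD_a": {"base": "stdPSD", "task": "a", "unit": "dB",            "direction": 1,  "subsystem": "articulation", "dysarthria_type": "ataxic",      "description": "standard deviation of band power spectral density"},
    "VD_s":     {"base": "VD",     "task": "s", "unit": "ms",            "direction": 1,  "subsystem": "timing",       "dysarthria_type": "ataxic",      "description": "vowel duration during syllable repetition"},
    "DDKI_s":   {"base": "DDKI",   "task": "s", "unit": "ms",            "direction": 1,  "subsystem": "timing",       "dysarthria_type": "ataxic",      "description": "diadochokinetic instability"},
    "PSI_a":    {"base": "PSI",    "task": "a", "unit": "%",             "direction": 1,  "subsystem": "phonation",    "dysarthria_type": "spastic",     "description": "proportion of sub-harmonic intervals"},
    "DDKR_s":   {"base": "DDKR",   "task": "s", "unit": "syll/s",        "direction": -1, "subsystem": "articulation", "dysarthria_type": "spastic",     "description": "diadochokinetic rate"},
    "NSR_t":    {"base": "NSR",    "task": "t", "unit": "syll/s",        "direction": -1, "subsystem": "timing",       "dysarthria_type": "spastic",     "description": "net speech rate"}
  }
}
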