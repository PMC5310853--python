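"""Bundled reference group summaries from a murine SAH vasospasm study.

Printed mean +/- SD summaries from an ex vivo micro-CT validation study of
vessel-cast murine cerebrovasculature (endovascular-perforation SAH model
vs. sham surgery, day 3). Diameters were measured at the proximal MCA (M1)
both microscopically on the brain samples and digitally on the
reconstructed trees; volumes are cylindrical-model volumes of the 1 mm ICA
+ 2.5 mm MCA segment. These summaries are the canonical inputs for the
treatment-study sample-size planning example.
"""

from __future__ import annotations

from .stats import GroupSummary

#: Microscopic M1 diameters (um)
MICROSCOPIC_DIAMETERS = {
    "left": {
        "sham": GroupSummary(n=6, mean=154.6, sd=14.8, label="left M1 microscopic, sham"),
        "sah": GroupSummary(n=8, mean=132.1, sd=29.8, label="left M1 microscopic, SAH"),
    },
    "right": {
        "sham": GroupSummary(n=6, mean=154.6, sd=23.9, label="right M1 microscopic, sham"),
        "sah": GroupSummary(n=9, mean=129.9, sd=28.2, label="right M1 microscopic, SAH"),
    },
}

#: Digitally reconstructed M1 diameters (um)
DIGITAL_DIAMETERS = {
    "left": {
        "sham": GroupSummary(n=6, mean=165.0, sd=18.7, label="left M1 digital, sham"),
        "sah": GroupSummary(n=8, mean=134.4, sd=26.9, label="left M1 digital, SAH"),
    },
    "right": {
        "sham": GroupSummary(n=6, mean=168.3, sd=17.7, label="right M1 digital, sham"),
        "sah": GroupSummary(n=9, mean=141.1, sd=31.8, label="right M1 digital, SAH"),
    },
}

#: Cylindrical-model volumes of the 1 mm ICA + 2.5 mm MCA segment (ul)
SEGMENT_VOLUMES = {
    "left": {
        "sham": GroupSummary(n=6, mean=0.07, sd=0.006, label="left segment volume, sham"),
        "sah": GroupSummary(n=8, mean=0.044, sd=0.017, label="left segment volume, SAH"),
    },
    "right": {
        "sham": GroupSummary(n=6, mean=0.073, sd=0.005, label="right segment volume, sham"),
        "sah": GroupSummary(n=9, mean=0.046, sd=0.013, label="right segment volume, SAH"),
    },
}

#: study bookkeeping: specimens, measurement sites, logged exclusions
N_SPECIMENS = 15  # 9 SAH + 6 sham
N_SITES = 5  # basilar midpoint, left/right ICA, left/right MCA
EXCLUSIONS = [
    ("SAH-left-ICA", "air bubble trapped in the intravascular cast"),
    ("SAH-left-MCA", "air bubble trapped in the intravascular cast"),
]
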