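"""Published Spearman correlation table for the trout dorsal/anal fins.

Used only to *check* recomputation from the SL50 fixture (the
``reproduce-correlations`` command and the test suite); the analysis itself
never reads these numbers.
Keys: ("dafpm", event, None) or ("eem", (endo_event, exo_event), fin).
"""

PUBLISHED_CORRELATIONS = {
    ("dafpm", 2, None): {
        "label": "proximal radial apparition", "n": 8, "rho": 0.8553628},
    ("dafpm", 3, None): {
        "label": "proximal radial chondrification", "n": 13,
        "rho": 0.9185589},
    ("dafpm", 4, None): {
        "label": "lepidotrichia apparition", "n": 15, "rho": 0.8604663},
    ("dafpm", 5, None): {
        "label": "distal radial apparition", "n": 12, "rho": 0.6288943},
    ("dafpm", 6, None): {
        "label": "distal radial chondrification", "n": 12,
        "rho": 0.9019622},
    ("dafpm", 7, None): {
        "label": "lepidotrichia segmentation", "n": 12, "rho": 0.6691664},
    ("dafpm", 8, None): {
        "label": "lepidotrichia ossification", "n": 15, "rho": 0.9576292},
    ("dafpm", 9, None): {
        "label": "lepidotrichia bifurcation", "n": 8, "rho": -0.40476},
    ("dafpm", 10, None): {
        "label": "proximal radial ossification", "n": 10,
        "rho": 0.9268293},
    # The apparition rows below could not be reconstructed exactly from
    # the printed SL50 values (the interaction of always-present proxies,
    # ns flags and the PR-to-L articulation is under-determined there);
    # they are checked qualitatively only (sign and rough magnitude).
    ("eem", (2, 4), "dorsal"): {
        "label": "PR and L apparition (D)", "n": 14, "rho": 0.903,
        "exact": False},
    ("eem", (2, 4), "anal"): {
        "label": "PR and L apparition (A)", "n": 12, "rho": 0.730,
        "exact": False},
    ("eem", (5, 4), "dorsal"): {
        "label": "L and DR apparition (D)", "n": 14, "rho": 0.972},
    ("eem", (5, 4), "anal"): {
        "label": "L and DR apparition (A)", "n": 12, "rho": 0.891},
    ("eem", (10, 8), "dorsal"): {
        "label": "L and PR ossification (D)", "n": 11, "rho": 0.854},
    ("eem", (10, 8), "anal"): {
        "label": "L and PR ossification (A)", "n": 11, "rho": 0.839},
}
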