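"""Scan-selection geometry of a 19-scan macular volume.

A 19-scan volume at 243 µm spacing is thinned to 9 analysable scans
(every other scan, keeping the central one). Each named sub-selection
picks positions among those 9; the mean distance between adjacent
selected scans tells how widely each selection samples the macula.
"""

from vitreoquant import SCHEME_NAMES, mean_selection_distance, select_scans, thin_every_other

analysable = thin_every_other(19)
print(f"analysable scans (original indices): {analysable}")
print(f"count: {len(analysable)}, central original scan: {analysable[4]}")
print()
print(f"{'scheme':>6} {'positions':>20} {'mean distance (um)':>20}")
for name in SCHEME_NAMES:
    scheme = select_scans(name)
    if len(scheme.indices) > 1:
        dist = f"{mean_selection_distance(scheme, 243.0):.0f}"
    else:
        dist = "n/a (single scan)"
    print(f"{name:>6} {str(list(scheme.indices)):>20} {dist:>20}")
print()
print("9 equally distributed scans sit 486 um apart; the 3 widely")
print("distributed scans (first, central, last) average 1944 um apart.")
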