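"""Identify unknown Bins against an MSP library with RI conversion.

A Bin generated from an unknown spectrum is matched against a library
whose retention indices are on the alkane (Kovats) scale; a second-order
polynomial calibration maps them onto the FAME RI scale first.
"""

from vocbin import (BinStore, LibraryEntry, Spectrum, alkane_to_fame,
                    fit_ri_calibration, identify_bins)

# calibration through three (Kovats, FAME RI) pairs; the outer two are the
# FAME C4/C24 anchors
cal = fit_ri_calibration([(726, 262_214), (1719, 621_574), (2712, 980_934)])
print(f"Kovats 1098 -> FAME RI {alkane_to_fame(cal, 1098):,.0f}")

linalool = Spectrum(((41, 400), (55, 250), (71, 999), (80, 150), (93, 700)))
library = [
    LibraryEntry("linalool", linalool, ri_alkane=1098.0),
    LibraryEntry("camphor", Spectrum(((81, 700), (95, 999), (152, 300))),
                 ri_alkane=1141.0),
]

store = BinStore()
unknown = store.add_bin(linalool, alkane_to_fame(cal, 1098.0) + 800.0, 71)

for bin_id, entry, score, d_ri in identify_bins(store, library, cal=cal):
    print(f"bin {bin_id}: {entry.name}  score={score}  deltaRI={d_ri:,.0f}")

# The linalool entry scores 1000 (same spectrum) at ~800 RI units away;
# camphor shares no fragments and never reaches the 700-point floor.
# Confirming an identity is explicit: store.set_identity(bin_id, name, ids).
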