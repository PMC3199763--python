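"""The tiered filter on a worked isomer case.

A linalool-like peak at FAME RI 446,700 (unique ion m/z 93) faces three
database Bins inside the +/-2,000 RI window.  The ion filter keeps the
two Bins sharing m/z 93; the adaptive similarity gate (the peak is pure,
so 800/1000 is demanded) rejects the wrong isomer; the survivor is
annotated.
"""

from vocbin import Spectrum, candidate_bins, required_similarity, similarity
from vocbin.models import DeconvolutedPeak
from vocbin.registry import Bin

linalool = Spectrum(((41, 400), (55, 250), (71, 999), (80, 150), (93, 700), (121, 300)))
terpinolene = Spectrum(((79, 300), (93, 999), (105, 250), (121, 850), (136, 700)))
other = Spectrum(((57, 999), (85, 500), (127, 300)))

bins = [
    Bin(1, linalool, 446_500.0, 93, frozenset({93, 71}), name="linalool"),
    Bin(2, terpinolene, 447_600.0, 93, frozenset({93, 121}), name="terpinolene"),
    Bin(3, other, 447_000.0, 57, frozenset({57})),
]
peak = DeconvolutedPeak("demo", 446.7, linalool, unique_mass=93,
                        apex_masses=frozenset({93}), sn=100.0, purity=0.1137,
                        unique_ion_height=25_000.0)

ri = 446_700.0
cands = candidate_bins(peak, ri, bins)
print("bins in RI window:", [b.bin_id for b in bins
                             if abs(b.ri - ri) <= 2000])
print("after unique-ion filter:", [(b.bin_id, b.name) for b in cands])

gate = required_similarity(peak.sn, peak.purity)
print(f"required similarity for this pure peak: {gate}")
for b in cands:
    print(f"  {b.name}: similarity {similarity(peak.spectrum, b.spectrum)}")

winner = [b for b in cands if similarity(peak.spectrum, b.spectrum) >= gate]
print("annotation:", winner[0].name)

# Three Bins pass the RI window, two share the unique ion, and only the
# true isomer clears the 800-point similarity gate.
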