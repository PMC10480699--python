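"""The DD:AD itinerancy metric from daily distance and home-range area.

A species' minimum annual travel distance (AD) is estimated as the
circumference of a circle whose area equals its annual home range; DD:AD
is the fraction of that circuit covered in a typical day.  Small values
mark itinerant, semi-nomadic rangers; values near or above 1 mark
sedentary species that patrol their whole range daily.
"""

import pandas as pd

import phylorange as pr

# illustrative (dd km/day, ahr km^2) pairs spanning the Carnivora range
species = {
    "sedentary_fox_like": (8.0, 3.0),
    "mustelid_like": (2.2, 3.0),
    "itinerant_bear_like": (10.0, 120_000.0),
}

rows = []
for name, (dd, ahr) in species.items():
    ad = pr.annual_travel_distance(ahr)
    rows.append({"species": name, "dd_km": dd, "ahr_km2": ahr,
                 "ad_km": round(ad, 1), "ddad": round(pr.ddad_ratio(dd, ahr), 3)})
print(pd.DataFrame(rows).to_string(index=False))
print()
print("ddad ~1: the species covers its estimated annual circuit daily "
      "(sedentary); ddad << 1: it uses a small fraction per day (itinerant).")

# the ratio is unit-free: miles and square miles give the same answer
km_per_mile = 1.609344
a = pr.ddad_ratio(8.0, 3.0)
b = pr.ddad_ratio(8.0 / km_per_mile, 3.0 / km_per_mile**2)
print(f"unit invariance: {a:.6f} (km) vs {b:.6f} (miles)")
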