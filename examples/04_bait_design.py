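"""Design capture baits from masked reference sequences and a hit table.

A toy input set exercises every rule of the pipeline: N-run cleaning and
T-padding, 120-mer tiling every 50 bp, soft-mask rejection, strict
length/identity hit filtering, and the melting-temperature specificity
bins (at most 10 off-target hits at 62.5-65 degC, at most 2 above 65).
"""

from toposcope.bait_design import design_baits
from toposcope.synthetic_data import make_bait_fixture

fixture = make_bait_fixture(seed=0)
candidates = design_baits(fixture.sequences, fixture.hits)

print(f"{'bait':14s} {'start':>5s} {'masked':>7s}  status")
for c in candidates:
    print(f"{c.bait_id:14s} {c.start:5d} {c.masked_fraction:7.2f}  {c.status}")

kept = [c for c in candidates if c.status == "retained"]
print(f"\n{len(candidates)} candidates, {len(kept)} retained")
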