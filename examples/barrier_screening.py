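"""Show how a screening barrier reshapes a single source's SPL field.

A 105 dBA source radiates hemispherically; a fully screening wall drops
every hidden receiver by 10 dB, and a receiver within 1 m of a reflective
facade gains 3 dB.  Printed numbers are per-source sound pressure levels
in dBA at a 30 m receiver.
"""

from noisewalk import Barrier, RectRegion, Screening, sound_power_watts
from noisewalk.acoustics import source_level

power = sound_power_watts(105.0)
src, rcv = (0.0, 5.0), (30.0, 5.0)

free = source_level(power, src, rcv)
wall = [Barrier(RectRegion(14.0, 0.0, 2.0, 10.0), Screening.FULL)]
screen = [Barrier(RectRegion(14.0, 0.0, 2.0, 10.0), Screening.PARTIAL)]
facade = [Barrier(RectRegion(30.5, 0.0, 2.0, 10.0), Screening.FULL, reflective=True)]

print(f"free field       : {free:.1f} dBA   (105 dBA source at 30 m)")
print(f"full screening   : {source_level(power, src, rcv, wall):.1f} dBA   (source hidden, -10 dB)")
print(f"partial screening: {source_level(power, src, rcv, screen):.1f} dBA   (source visible, -5 dB)")
print(f"near facade      : {source_level(power, src, rcv, facade):.1f} dBA   (reflection, +3 dB)")
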