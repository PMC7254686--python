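"""Closed-form speed prediction from a single trackway stride length.

Takes the fastest observed walking stride of a Svalbard rock ptarmigan
(0.35 m) and its literature hip height (0.1727 m), and prints the Froude
number, relative stride length, and the speed each general predictor
implies.  The relative stride of 2.03 sits just past the classical
walk/trot boundary of 2.0 — a bird that was in fact walking would be
diagnosed as trotting from its stride alone.
"""

from trackway import (
    SpeciesProfile,
    alexander_speed,
    froude,
    froude_model_speed,
    relative_stride,
    thulborn_wade_speed,
    trot_speed,
)

profile = SpeciesProfile()  # ptarmigan: h = 0.1727 m, g = 9.81 m/s^2
l_stride = 0.35             # m, fastest recorded walking stride
u_video = 0.92              # m/s, simultaneous video ground truth

print(f"stride length        : {l_stride:.3f} m")
print(f"relative stride      : {float(relative_stride(l_stride, profile)):.2f}")
print(f"Froude number (video): {froude(u_video, profile).fr:.2f}")
print(f"walking predictor    : {alexander_speed(l_stride, profile):.3f} m/s")
print(f"fast-gait predictor  : {thulborn_wade_speed(l_stride, profile):.3f} m/s")
print(f"trot (mean of two)   : {trot_speed(l_stride, profile):.3f} m/s")
u, band = froude_model_speed(l_stride, profile)
print(f"piecewise model      : {u:.3f} m/s in the {band!r} band")
print(f"video-measured speed : {u_video:.2f} m/s")
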