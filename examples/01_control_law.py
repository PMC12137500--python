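"""The threshold-plus-proportional control law on worked points.

With signed error diff = measured - target: full power below target - 1.0 degC,
reduced drive (default: laser off) above target + 0.6 degC, and in between
output% = (50 + g) - diff * (50 - g), where g is 0 for fast-heating samples
and 30 for slow ones.
"""

from thermoloop import ControllerConfig, LaserCalibration, control_step

cfg = ControllerConfig(target_temp=42.5)
cal = LaserCalibration()

print("target 42.5 degC; band [41.5, 43.1] degC")
for measured, g in [(41.0, 0.0), (41.5, 0.0), (42.5, 0.0), (42.5, 30.0), (43.0, 30.0), (43.2, 30.0)]:
    pct = control_step(measured, cfg, g)
    print(f"  measured {measured:5.1f} degC, g={g:2.0f} -> {pct:5.1f} %  ({cal.percent_to_power(pct):.2f} W)")
print("50 % at zero error with g=0, 80 % with g=30; the law is continuous at the")
print("lower band edge (100 %) and drops to the floor above the upper edge.")
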