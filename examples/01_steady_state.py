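"""Evaluate one sensor's steady state and headline performance metrics."""

from mirsense import SensorParameters, performance_summary, sensor_ic50, steady_state

params = SensorParameters.basic()

for input_level in (0.0, 20.0, 3000.0):
    state = steady_state(params, input_level)
    print(
        f"input {input_level:>7.1f} molecules/cell -> "
        f"activator {state.activator:9.1f}, miR-FF4 {state.mirff4:8.2f}, "
        f"output {state.output:9.1f}"
    )

summary = performance_summary(params, sensor_ic50=sensor_ic50(params))
print()
print(f"Off state            : {summary.off_state:9.1f} molecules/cell")
print(f"practical On (3000)  : {summary.practical_on:9.1f} molecules/cell")
print(f"theoretical On       : {summary.theoretical_on:9.1f} molecules/cell")
print(f"dynamic range (pract): {summary.dynamic_range_practical:9.2f}")
print(f"dynamic range (theor): {summary.dynamic_range_theoretical:9.2f}")
print(f"sensor IC50          : {summary.sensor_ic50:9.1f} molecules/cell")

# The Off state is the repressed output at zero input; the practical
# dynamic range (~38-fold) is what a highly expressed endogenous miRNA
# can elicit, while the theoretical one (~74-fold) needs saturating input.
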