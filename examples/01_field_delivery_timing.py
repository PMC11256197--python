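"""Build the standard 5x7 spot field and time its FLASH and CONV deliveries.

The same spot map is delivered two ways: painted once at a 60 Gy/s field
dose rate (FLASH), or repainted hundreds of times with 4.4 ms pauses to
reach ~0.35 Gy/s (CONV). The field dose rate is the prescribed dose over
the total field duration, pauses included.
"""

from flashtox import (
    build_field_plan,
    field_dose_rate,
    repaints_for_dose,
    schedule_conv,
    schedule_flash,
)

plan = build_field_plan(rows=5, cols=7, spacing=6.0, rim_factor=1.4, sigma=8.0)
print(f"field: {plan.n_spots} spots, extents {plan.extents()[0]:.0f} x "
      f"{plan.extents()[1]:.0f} mm, rim spots at weight {plan.rim_factor}")

flash = schedule_flash(plan, prescribed_dose=40.0, field_dose_rate=60.0)
print(f"FLASH 40 Gy: {len(flash.events)} spot events in "
      f"{flash.total_duration:.3f} s -> field dose rate "
      f"{field_dose_rate(flash):.1f} Gy/s")

n_rep = repaints_for_dose(30.0)
conv = schedule_conv(plan, prescribed_dose=30.0, field_dose_rate=0.35,
                     n_repaints=n_rep)
print(f"CONV 30 Gy: {n_rep} repaints -> {len(conv.events)} spot events in "
      f"{conv.total_duration:.1f} s -> field dose rate "
      f"{field_dose_rate(conv):.2f} Gy/s")
print("The CONV delivery stretches the same spot pattern over minutes; the")
print("FLASH delivery finishes in under a second at the same dose per spot.")
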