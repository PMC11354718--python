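[geometry]
dish_inner_diameter = 96.0
dish_height = 30.0
dish_wall_thickness = 2.0
slab_length = 40.0
slab_width = 40.0
slab_height = 20.0
slab_top_offset = 4.0
electrode_diameter = 0.63
electrode_length = 8.0
electrode_gap = 1.37
electrode_tip_contact = true

[recipe]
amplitude = 300.0
phase_duration_us = 10.0
frequency_hz = 10.0
pulse_count = 100
interphase_delay_ns = 500.0
polarity = "biphasic"

[solver]
spacing_mm = 0.1
tolerance = 1e-08
half_extent_x_mm = 8.0
half_extent_y_mm = 6.0
depth_mm = 10.0
electrode_model = "equipotential"

[materials.bath]
conductivity = 1.8
relative_permittivity = 1.0

[materials.slab]
conductivity = 0.04
relative_permittivity = 1.0

[materials.electrode_a]
conductivity = 0.00174
relative_permittivity = 1.0

[materials.electrode_b]
conductivity = 0.00174
relative_permittivity = 1.0
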