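# Default optical and acoustic properties per tissue / material class.
#
# Values follow the conventions of standard tissue-optics compilations
# (Jacques-style): a melanin-bearing dermis, a fat-dominated subcutis,
# muscle-like bulk tissue, and an essentially transparent coupling stack.
# Edit this file to substitute site-specific property tables.
#
# Units:
#   blood_volume_fraction, so2, water_fraction, fat_fraction,
#   melanin_fraction        dimensionless fractions in [0, 1]
#   mus500                  reduced scattering coefficient at 500 nm (per mm)
#   scattering_power        exponent b in mus'(lambda) = mus500*(lambda/500)^-b
#   gruneisen               dimensionless thermoelastic efficiency
#   speed_of_sound          mm per microsecond
#   density                 kg per m^3
#   acoustic_attenuation    dB per MHz per cm

coupling_medium:
  blood_volume_fraction: 0.0
  so2: 0.0
  water_fraction: 0.0        # heavy-water-like coupling: negligible NIR absorption
  fat_fraction: 0.0
  melanin_fraction: 0.0
  mus500: 0.0
  scattering_power: 1.0
  gruneisen: 0.0
  speed_of_sound: 1.48
  density: 1000.0
  acoustic_attenuation: 0.0022

membrane:
  blood_volume_fraction: 0.0
  so2: 0.0
  water_fraction: 0.05
  fat_fraction: 0.0
  melanin_fraction: 0.0
  mus500: 0.0
  scattering_power: 1.0
  gruneisen: 0.0
  speed_of_sound: 1.54
  density: 1100.0
  acoustic_attenuation: 0.1

ultrasound_gel:
  blood_volume_fraction: 0.0
  so2: 0.0
  water_fraction: 0.9
  fat_fraction: 0.0
  melanin_fraction: 0.0
  mus500: 0.0
  scattering_power: 1.0
  gruneisen: 0.0
  speed_of_sound: 1.52
  density: 1020.0
  acoustic_attenuation: 0.02

dermis:
  blood_volume_fraction: 0.01
  so2: 0.7
  water_fraction: 0.65
  fat_fraction: 0.0
  # melanosome fraction of a thin epidermis (~1-2 % over ~0.1 mm) smeared
  # over the full dermis layer thickness
  melanin_fraction: 0.002
  mus500: 4.6
  scattering_power: 1.42
  gruneisen: 0.2
  speed_of_sound: 1.58
  density: 1109.0
  acoustic_attenuation: 0.65

subcutis:
  blood_volume_fraction: 0.005
  so2: 0.7
  water_fraction: 0.3
  fat_fraction: 0.6
  melanin_fraction: 0.0
  mus500: 3.0
  scattering_power: 0.9
  gruneisen: 0.65
  speed_of_sound: 1.45
  density: 950.0
  acoustic_attenuation: 0.6

bulk_tissue:
  blood_volume_fraction: 0.02
  so2: 0.7
  water_fraction: 0.75
  fat_fraction: 0.05
  melanin_fraction: 0.0
  mus500: 1.1
  scattering_power: 0.93
  gruneisen: 0.2
  speed_of_sound: 1.58
  density: 1090.0
  acoustic_attenuation: 1.0

lymph_node:
  # blood_volume_fraction and so2 are overridden per phantom by the
  # sampled node ground truth; the values here are only placeholders.
  blood_volume_fraction: 0.09
  so2: 0.58
  water_fraction: 0.8
  fat_fraction: 0.02
  melanin_fraction: 0.0
  mus500: 1.0
  scattering_power: 1.0
  gruneisen: 0.2
  speed_of_sound: 1.54
  density: 1035.0
  acoustic_attenuation: 0.8
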