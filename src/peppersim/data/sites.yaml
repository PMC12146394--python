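# Synthetic site registry for the multi-site warming-scenario analysis.
#
# The nine pepper-growing sites mirror the provinces of the open-field
# survey, but their heat-unit requirements (PHU, C day) and weather are
# synthetic stand-ins: PHUs are assigned from the survey's regional pattern
# (cooler mountainous northeast ~1500-1600, west/central ~1700, milder
# south ~1800) and daily weather comes from the seeded latitude-band
# generator, not from any station record.
sites:
  - {id: hoengseong, province: GW, city: Hoengseong, band: northern, phu: 1500}
  - {id: anseong,    province: GG, city: Anseong,    band: central,  phu: 1600}
  - {id: jecheon,    province: CB, city: Jecheon,    band: northern, phu: 1600}
  - {id: dangjin,    province: CN, city: Dangjin,    band: central,  phu: 1700}
  - {id: cheongyang, province: CN, city: Cheongyang, band: central,  phu: 1700}
  - {id: yeongyang,  province: GB, city: Yeongyang,  band: northern, phu: 1500}
  - {id: hamyang,    province: GN, city: Hamyang,    band: southern, phu: 1800}
  - {id: sinan,      province: JN, city: Sinan,      band: southern, phu: 1800}
  - {id: haenam,     province: JN, city: Haenam,     band: southern, phu: 1800}
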