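# Example dating-clock configuration.
#
# locus_rates: Y-STR mutation rates in mutations/locus/generation.  The
# values below are editable placeholders in the range of published
# father-son estimates (Ballantyne et al. 2010); replace them with the
# rates appropriate to your marker panel before dating real data.
#
# dating_loci: the 8-marker panel used for variance dating.  The canonical
# choice is the eight Yfiler markers with the longest duration of linearity
# with time (Busby et al. 2011); the placeholder panel below simply lists
# eight common single-copy Yfiler loci and MUST be reviewed per study.
#
# hvs_rate_years_per_mutation: HVS-I clock calibration in years per
# observed mutation (Soares et al. 2009 style).  It has no package default;
# supply your calibration explicitly.
generation_years: 25
hvs_rate_years_per_mutation: null
dating_loci:
  - DYS19
  - DYS389I
  - DYS389b
  - DYS390
  - DYS391
  - DYS392
  - DYS393
  - DYS437
locus_rates:
  DYS19: 0.0015
  DYS389I: 0.0025
  DYS389b: 0.0030
  DYS390: 0.0021
  DYS391: 0.0026
  DYS392: 0.0004
  DYS393: 0.0011
  DYS437: 0.0012
  DYS438: 0.0004
  DYS439: 0.0048
  DYS448: 0.0002
  DYS456: 0.0042
  DYS458: 0.0064
  DYS635: 0.0038
  GATAH4: 0.0028
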