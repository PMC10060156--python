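# Catalogue of synthetic study conditions.
#
# Each scenario defines reference panels (Balding-Nichols, optionally sharing
# a clade ancestor so that right panels are differentially related to the
# sources) and one admixed cohort with sex-specific source contributions.
# Autosomal proportions are C_A = (m+f)/2, X proportions C_X = (2f+m)/3.

mtwapa-like:
  description: >
    Three-way coastal cohort: 57% African / 36% Persian / 7% Indian autosomal
    ancestry with strongly male-biased Persian and female-biased African
    contributions, 30 generations since the admixture pulse.
  n_snps: 50000
  clade_F: 0.05
  populations:
    African:    {drift_F: 0.02, n: 30, clade: african}
    Persian:    {drift_F: 0.02, n: 30, clade: persian}
    Indian:     {drift_F: 0.02, n: 30, clade: indian}
    R_African:  {drift_F: 0.02, n: 30, clade: african}
    R_Persian:  {drift_F: 0.02, n: 30, clade: persian}
    R_Indian:   {drift_F: 0.02, n: 30, clade: indian}
    Outgroup1:  {drift_F: 0.10, n: 30}
    Outgroup2:  {drift_F: 0.08, n: 30}
  rights: [Outgroup1, R_African, R_Persian, R_Indian, Outgroup2]
  admixed:
    name: Coastal
    sources: [African, Persian, Indian]
    # C_A = (0.57, 0.36, 0.07); C_X = (0.687, 0.253, 0.06)
    female_fractions: [0.92, 0.04, 0.04]
    male_fractions:   [0.22, 0.68, 0.10]
    generations: 30
    n: 200

two-source:
  description: >
    Sex-balanced two-way mixture (50/50 African/Persian) 30 generations old;
    the default cohort for ancestry-covariance-decay dating.
  n_snps: 50000
  clade_F: 0.05
  populations:
    African:    {drift_F: 0.02, n: 30, clade: african}
    Persian:    {drift_F: 0.02, n: 30, clade: persian}
    R_African:  {drift_F: 0.02, n: 30, clade: african}
    R_Persian:  {drift_F: 0.02, n: 30, clade: persian}
    Outgroup1:  {drift_F: 0.10, n: 30}
    Outgroup2:  {drift_F: 0.08, n: 30}
  rights: [Outgroup1, R_African, R_Persian, Outgroup2]
  admixed:
    name: Admixed
    sources: [African, Persian]
    female_fractions: [0.5, 0.5]
    male_fractions:   [0.5, 0.5]
    generations: 30
    n: 200

sex-biased:
  description: >
    Two-way mixture where source 1 contributed 90% of female-side and 10% of
    male-side ancestors ((f, m) = (0.9, 0.1)); used to validate the
    X-vs-autosome sex-bias inference end to end.
  n_snps: 20000
  clade_F: 0.05
  populations:
    African:    {drift_F: 0.02, n: 30, clade: african}
    Persian:    {drift_F: 0.02, n: 30, clade: persian}
    R_African:  {drift_F: 0.02, n: 30, clade: african}
    R_Persian:  {drift_F: 0.02, n: 30, clade: persian}
    Outgroup1:  {drift_F: 0.10, n: 30}
    Outgroup2:  {drift_F: 0.08, n: 30}
  rights: [Outgroup1, R_African, R_Persian, Outgroup2]
  admixed:
    name: Admixed
    sources: [African, Persian]
    female_fractions: [0.9, 0.1]
    male_fractions:   [0.1, 0.9]
    generations: 20
    n: 150

mixed-asian-source:
  description: >
    Target admixed between an African source and a single proximal source
    that is itself 88% Persian / 12% Indian; used by the mixed-source
    Hotelling grid to locate the Persian share of the Asian side.
  n_snps: 50000
  clade_F: 0.05
  populations:
    African:    {drift_F: 0.02, n: 30, clade: african}
    Persian:    {drift_F: 0.02, n: 30, clade: persian}
    Indian:     {drift_F: 0.02, n: 30, clade: indian}
    R_African:  {drift_F: 0.02, n: 30, clade: african}
    R_Persian:  {drift_F: 0.02, n: 30, clade: persian}
    R_Indian:   {drift_F: 0.02, n: 30, clade: indian}
    Outgroup1:  {drift_F: 0.10, n: 30}
    Outgroup2:  {drift_F: 0.08, n: 30}
  rights: [Outgroup1, R_African, R_Persian, R_Indian, Outgroup2]
  admixed:
    name: Coastal
    sources: [African, Persian, Indian]
    # Asian side split 88/12 Persian/Indian: C_A = (0.55, 0.396, 0.054)
    female_fractions: [0.55, 0.396, 0.054]
    male_fractions:   [0.55, 0.396, 0.054]
    generations: 30
    n: 200
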