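# PPI trigger lexicon: one surface variant per line, tab-separated with its
# trigger family.  Eleven families; every variant belongs to exactly one.
# The table is editable: adding a row extends matching without code changes.
binding	binding
bind	binding
binds	binding
bound	binding
rebinding	binding
interaction	interaction
interactions	interaction
interact	interaction
interacts	interaction
interacted	interaction
interacting	interaction
complex	complex
complexes	complex
complexed	complex
association	association
associations	association
associate	association
associates	association
associated	association
associating	association
dissociation	dissociation
dissociate	dissociation
dissociates	dissociation
dissociated	dissociation
dissociating	dissociation
dimerization	dimerization
dimerisation	dimerization
dimerize	dimerization
dimerizes	dimerization
dimerized	dimerization
dimerizing	dimerization
homodimerization	dimerization
heterodimerization	dimerization
homodimerize	dimerization
homodimerizes	dimerization
heterodimerize	dimerization
heterodimerizes	dimerization
affinity	affinity
affinities	affinity
precipitation	precipitation
precipitate	precipitation
precipitates	precipitation
precipitated	precipitation
precipitating	precipitation
co-precipitation	precipitation
coprecipitation	precipitation
co-precipitate	precipitation
co-precipitates	precipitation
co-precipitated	precipitation
coprecipitate	precipitation
coprecipitates	precipitation
coprecipitated	precipitation
immunoprecipitation	precipitation
co-immunoprecipitation	precipitation
co-immunoprecipitated	precipitation
co-immunoprecipitates	precipitation
immunoprecipitated	precipitation
recruitment	recruitment
recruit	recruitment
recruits	recruitment
recruited	recruitment
recruiting	recruitment
release	release
releases	release
released	release
releasing	release
sequestering	sequestering
sequestration	sequestering
sequester	sequestering
sequesters	sequestering
sequestered	sequestering
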