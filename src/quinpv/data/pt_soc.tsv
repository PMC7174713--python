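preferred_term	soc_code
tremor	nervous
paraesthesia	nervous
paresthesia	nervous
headache	nervous
syncope	nervous
pre-syncope	nervous
presyncope	nervous
formication	nervous
dizziness	nervous
ageusia	nervous
memory loss	nervous
anosmia	nervous
epilepsy	nervous
altered state of consciousness	nervous
metallic taste	nervous
paralysis	nervous
peripheral neuropathy	nervous
decreased level of consciousness	nervous
sudden fall	nervous
hypotonia	nervous
afasia	nervous
aphasia	nervous
drowsiness	nervous
akathisia	nervous
burning sensation	nervous
cerebral ischemia	nervous
balance disorder	nervous
hemiparesis	nervous
myalgia	musculoskeletal
arthralgia	musculoskeletal
tendinitis	musculoskeletal
limb pain	musculoskeletal
tendon pain	musculoskeletal
musculoskeletal pain	musculoskeletal
rhabdomyolysis	musculoskeletal
arthromyalgia	musculoskeletal
hypercreatininemia	musculoskeletal
muscle rigidity	musculoskeletal
muscle tension	musculoskeletal
muscle inflammation	musculoskeletal
muscle weakness	musculoskeletal
tendon rupture	musculoskeletal
insomnia	psychiatric
hallucination	psychiatric
confusional state	psychiatric
confusion	psychiatric
agitation	psychiatric
temporospatial disorientation	psychiatric
restlessness	psychiatric
irritability	psychiatric
acute psychosis	psychiatric
anxiety	psychiatric
drug abuse	psychiatric
dyssomnia	psychiatric
mood swing	psychiatric
auditory hallucination	psychiatric
mental disorder	psychiatric
psychotic disorder	psychiatric
panic attack	psychiatric
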