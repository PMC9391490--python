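taxon,diet,body_mass_kg,longevity_days_override,rate_days_override,note
Mesenosaurus,hypercarnivore,5,75,41,taxon-level averages reported directly; per-family counts unpublished; mass package-estimated
Dimetrodon,hypercarnivore,120,,,mass package-estimated
Haptodus,carnivore,25,,,mass package-estimated
Watongia,carnivore,90,,,mass package-estimated
Oromycter,herbivore,10,,,mass package-estimated
Ennatosaurus,herbivore,200,,,mass package-estimated
Edaphosaurus,herbivore,150,,,mass package-estimated
Delorhynchus,insectivore,0.2,,,mass package-estimated
Colobomycter,insectivore,0.3,,,mass package-estimated
Captorhinus,omnivore,0.6,,,mass package-estimated
Opisthodontosaurus,insectivore,0.3,,,mass package-estimated
Seymouria,carnivore,4,,,mass package-estimated
Varanus_bengalensis,carnivore,7,,,mass package-estimated
Varanus_komodoensis,carnivore,80,,,mass package-estimated
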