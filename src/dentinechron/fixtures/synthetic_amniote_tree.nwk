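(Seymouria:56,(((Delorhynchus:6,Colobomycter:6):20,((Captorhinus:7,Opisthodontosaurus:1):20,(Varanus_bengalensis:180,Varanus_komodoensis:180):130):5):5,((Oromycter:11,Ennatosaurus:33):12,((Mesenosaurus:6,Watongia:30):13,(Edaphosaurus:26,(Haptodus:2,Dimetrodon:19):3):3):4):8):15);
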