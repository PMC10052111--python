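group,total_workers,exposed_low,exposed_high,mean_exposed
construction_finishing,25300,2500,9000,5700
motor_vehicle_service_repair,22000,8100,10600,9300
assemblers_machinery_electric,14600,1500,1500,1500
furniture_manufacture,5300,500,1000,800
plastic_product_process,4000,800,1000,900
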